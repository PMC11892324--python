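"""Seeded synthetic multi-ancestry biobank generator.

Emulates the statistical structure a proxy-phenotype rare-variant study
assumes: a latent log liver-fat trait (log-PDFF) driven by metabolic
features and planted genetic effects; an imaging subsample covering <10% of
the cohort; ICD-style MASLD labels that underdiagnose true cases by ~42-45%;
cardiometabolic criteria and exclusionary diagnoses; lab-to-imaging time
gaps that decorrelate lab features from the imaging-day truth; and
multi-ancestry allele-frequency structure including ancestry-restricted
ultra-rare variants.  Every stage is seeded and returns a truth manifest so
parameter recovery is testable end to end.

Default calibration targets the printed descriptive statistics of the
UK-Biobank imaging cohort: median PDFF ~2.9% and steatosis (PDFF >= 5.5%)
prevalence ~21%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

ANCESTRIES = ("EUR", "AFR", "AMR", "SAS", "EAS", "MID")

# EUR fraction exactly as printed; the published non-EUR fractions sum to
# 0.206 with ~5% of participants unassigned, so the remaining five are
# rescaled proportionally to fill the complement.
_RAW = {"EUR": 0.743, "AFR": 0.099, "AMR": 0.073, "SAS": 0.018, "EAS": 0.013, "MID": 0.003}
_NON_EUR_SCALE = (1 - _RAW["EUR"]) / sum(v for k, v in _RAW.items() if k != "EUR")
DEFAULT_PROPORTIONS = {
    k: (v if k == "EUR" else v * _NON_EUR_SCALE) for k, v in _RAW.items()
}

FREQ_CLASS_RANGES = {
    "common": (0.01, 0.5),
    "rare": (1e-4, 0.01),
    "ultra_rare": (1e-5, 1e-4),
}

DELETERIOUSNESS_FLAGS = (
    "polyphen2_humvar",
    "polyphen2_humdiv",
    "sift",
    "lrt",
    "mutation_taster",
)

# feature panel: 20 named features, a desk-scale analogue of a 183-feature
# biobank panel.  (name, category, factor loading on the latent metabolic
# factor, trait loading sign).  The six leading features carry the signs seen
# in attribution analyses of liver-fat predictors: SHBG and AST/ALT ratio
# negative, BMI/waist/leg-fat/triglycerides positive.
FEATURE_PANEL = [
    # name, category, a_f (corr with metabolic factor), trait loading w_f
    ("bmi", "physical", 0.80, 0.30),
    ("waist_circumference", "physical", 0.78, 0.28),
    ("leg_fat_pct", "physical", 0.65, 0.22),
    ("shbg", "lab", -0.55, -0.20),
    ("triglycerides", "lab", 0.60, 0.20),
    ("ast_alt_ratio", "lab", -0.45, -0.16),
    ("alt", "lab", 0.50, 0.10),
    ("ast", "lab", 0.35, 0.05),
    ("ggt", "lab", 0.40, 0.06),
    ("alp", "lab", 0.15, 0.02),
    ("glucose", "lab", 0.45, 0.05),
    ("hba1c", "lab", 0.45, 0.04),
    ("hdl_cholesterol", "lab", -0.50, -0.05),
    ("ldl_cholesterol", "lab", 0.25, 0.02),
    ("igf1", "lab", -0.20, -0.02),
    ("crp", "lab", 0.35, 0.03),
    ("body_fat_pct", "physical", 0.70, 0.10),
    ("hip_circumference", "physical", 0.60, 0.05),
    ("diastolic_bp", "physical", 0.30, 0.0),
    ("smoking_pack_years", "lifestyle", 0.10, 0.0),
]
REQUIRED_FEATURES = ("bmi", "waist_circumference", "alt", "ast", "triglycerides")
LAB_FEATURES = tuple(n for n, c, _, _ in FEATURE_PANEL if c == "lab")

# ancestry-specific principal-component means (10 PCs); crude cluster
# separation is all downstream covariate adjustment needs
_PC_MEANS = {
    anc: np.array([np.cos(i * (j + 1)) * 3.0 / (j + 1) for j in range(10)])
    for i, anc in enumerate(ANCESTRIES)
}


@dataclass(frozen=True)
class AncestryMix:
    """Ancestry labels, cohort proportions, and per-ancestry allele-frequency
    multipliers (logit-scale shifts applied on top of the shared base AF)."""

    labels: tuple[str, ...] = ANCESTRIES
    proportions: tuple[float, ...] = tuple(DEFAULT_PROPORTIONS[a] for a in ANCESTRIES)
    af_logit_shift: tuple[float, ...] = (0.0, 0.3, 0.15, 0.1, 0.1, 0.05)

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ancestry labels must be unique")
        if len(self.labels) != len(self.proportions):
            raise ValueError("labels and proportions length mismatch")
        if abs(sum(self.proportions) - 1.0) > 1e-12:
            raise ValueError(f"proportions must sum to 1, got {sum(self.proportions)!r}")


@dataclass(frozen=True)
class VariantSpec:
    """Counts and structure of the simulated variant panel."""

    n_common: int = 200
    n_rare: int = 300
    n_ultra_rare: int = 400
    n_genes: int = 40
    ptv_fraction: float = 0.35
    missense_fraction: float = 0.45
    deleterious_all5_fraction: float = 0.5
    logit_af_corr: float = 0.8
    n_afr_only_ultra_rare: int = 2
    n_chromosomes: int = 22

    def __post_init__(self):
        if min(self.n_common, self.n_rare, self.n_ultra_rare) < 0:
            raise ValueError("variant counts must be non-negative")
        if not 0 < self.logit_af_corr <= 1:
            raise ValueError("logit_af_corr must lie in (0, 1]")


@dataclass(frozen=True)
class EffectConfig:
    """Planted effects and observation model for the latent trait.

    Effects are per ALT allele on latent log-PDFF (log-% fat fraction).
    Sensitivity is the probability that an eligible true case carries an
    ICD diagnosis (the published underdiagnosis of 42-45% motivates the
    0.565 default); specificity is fixed at 1 (no over-diagnosis) unless
    ``false_positive_rate`` is raised.
    """

    intercept: float = math.log(2.87)
    feature_signal_sd: float = 0.35
    residual_sd: float = 0.727
    n_causal_common: int = 2
    beta_common: float = 0.05
    n_causal_rare: int = 3
    beta_rare: float = 0.15
    n_causal_genes: int = 2
    beta_gene: float = 0.6
    female_effect_multiplier: float = 1.0
    diagnosis_sensitivity: float = 0.565
    false_positive_rate: float = 0.0
    imaging_fraction: float = 0.09
    cardiometabolic_rate: float = 0.95
    exclusionary_rate: float = 0.02
    time_gap_max_years: float = 14.0
    lab_drift_per_year: float = 0.03
    # liver-responsive labs are downstream of liver fat: they pick up part of
    # the genetic + idiosyncratic trait component, which is what lets a
    # feature-based proxy phenotype carry genetic signal at all
    biomarker_feedback: float = 0.28
    # fraction of each planted effect routed through the metabolic factor
    # (adiposity / insulin-resistance pathway, visible to the feature panel)
    # rather than acting hepatic-direct; the total per-allele effect on the
    # latent trait is beta_true either way
    upstream_effect_share: float = 0.6
    feature_missing_rate: float = 0.10
    steatosis_threshold: float = 5.5

    def __post_init__(self):
        if not 0 < self.diagnosis_sensitivity <= 1:
            raise ValueError("diagnosis sensitivity must lie in (0, 1]")
        if not 0 < self.imaging_fraction < 1:
            raise ValueError("imaging fraction must lie in (0, 1)")
        if self.residual_sd <= 0:
            raise ValueError("residual SD must be positive")


@dataclass
class SimTruth:
    """Recovery oracle: everything the generator planted."""

    seed: int
    causal_variants: dict[str, float]
    causal_genes: dict[str, float]
    latent_log_pdff: np.ndarray
    true_steatosis: np.ndarray
    feature_loadings: dict[str, float]
    config: EffectConfig

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "causal_variants": self.causal_variants,
            "causal_genes": self.causal_genes,
            "feature_loadings": self.feature_loadings,
            "config": asdict(self.config),
            "n_participants": int(len(self.latent_log_pdff)),
            "n_true_steatosis": int(self.true_steatosis.sum()),
        }


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------

def simulate_participants(n: int, mix: AncestryMix | None = None, seed: int = 0) -> pd.DataFrame:
    """Cohort table: id, ancestry, age, sex, 10 PCs, alcohol g/week, fasting time."""
    if n < 1:
        raise ValueError("cohort size must be positive")
    mix = mix or AncestryMix()
    rng = np.random.default_rng(seed)
    anc = rng.choice(mix.labels, size=n, p=mix.proportions)
    pcs = np.vstack([_PC_MEANS.get(a, np.zeros(10)) for a in anc]) + rng.normal(0, 1, (n, 10))
    cohort = pd.DataFrame(
        {
            "participant_id": [f"P{i:07d}" for i in range(n)],
            "ancestry": anc,
            "age": np.clip(rng.normal(57, 8, n), 40, 70).round(1),
            "sex": rng.integers(0, 2, n),  # 1 = female
            "alcohol_g_week": rng.gamma(1.5, 60, n).round(1),
            "fasting_time_h": rng.uniform(2, 12, n).round(1),
        }
    )
    for j in range(10):
        cohort[f"pc{j + 1}"] = pcs[:, j]
    return cohort.set_index("participant_id")


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def _draw_class_afs(rng, n, lo, hi, shifts, corr):
    """Per-ancestry AFs sharing a base frequency, correlated on the logit
    scale with the requested cross-ancestry correlation, clipped to the
    class range in every ancestry."""
    l_lo, l_hi = logit(lo), logit(hi)
    base = rng.uniform(l_lo, l_hi, n)
    sd_base = (l_hi - l_lo) / math.sqrt(12)
    tau = sd_base * math.sqrt((1 - corr) / corr)
    out = {}
    for anc, shift in shifts.items():
        z = base + shift * sd_base * 0.2 + rng.normal(0, tau, n)
        out[anc] = np.clip(expit(z), lo, np.nextafter(hi, 0))
    return out


def simulate_variants(
    spec: VariantSpec | None = None,
    mix: AncestryMix | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Variant table with per-ancestry AFs, consequences, deleteriousness
    flags and gene membership.

    Ultra-rare variants stay below 1e-4 in every ancestry; a configurable
    number of ultra-rare variants are polymorphic only among AFR ancestry
    participants (AF 0 elsewhere).  Rare and ultra-rare variants are
    distributed over genes round-robin so genes accumulate enough qualifying
    variants for cumulative-MAC masks.
    """
    spec = spec or VariantSpec()
    mix = mix or AncestryMix()
    rng = np.random.default_rng(seed)
    shifts = dict(zip(mix.labels, mix.af_logit_shift))
    rows = []
    counts = {"common": spec.n_common, "rare": spec.n_rare, "ultra_rare": spec.n_ultra_rare}
    gene_names = [f"GENE{i:04d}" for i in range(spec.n_genes)] if spec.n_genes else []
    gene_cursor = 0
    vid = 0
    bases = np.array(list("ACGT"))
    for cls, cnt in counts.items():
        if cnt == 0:
            continue
        lo, hi = FREQ_CLASS_RANGES[cls]
        afs = _draw_class_afs(rng, cnt, lo, hi, shifts, spec.logit_af_corr)
        for i in range(cnt):
            if cls == "common":
                consequence, gene = "other", ""
            else:
                u = rng.random()
                if u < spec.ptv_fraction:
                    consequence = rng.choice(
                        ["stop_gained", "frameshift", "splice_donor", "splice_acceptor",
                         "transcript_ablation"]
                    )
                elif u < spec.ptv_fraction + spec.missense_fraction:
                    consequence = "missense"
                else:
                    consequence = "other"
                gene = gene_names[gene_cursor % len(gene_names)] if gene_names else ""
                gene_cursor += 1
            if consequence == "missense" and rng.random() < spec.deleterious_all5_fraction:
                flags = {f: True for f in DELETERIOUSNESS_FLAGS}
            else:
                flags = {f: bool(rng.random() < 0.5) for f in DELETERIOUSNESS_FLAGS}
            ref, alt = rng.choice(bases, 2, replace=False)
            chrom = (vid % spec.n_chromosomes) + 1
            row = {
                "variant_id": f"{chrom}:{100000 + vid * 137}:{ref}:{alt}",
                "chrom": chrom,
                "pos": 100000 + vid * 137,
                "ref": ref,
                "alt": alt,
                "gene": gene,
                "consequence": consequence,
                "freq_class": cls,
                **flags,
            }
            for anc in mix.labels:
                row[f"af_{anc}"] = float(afs[anc][i])
            rows.append(row)
            vid += 1
    table = pd.DataFrame(rows)
    if len(table) == 0:
        cols = ["variant_id", "chrom", "pos", "ref", "alt", "gene", "consequence",
                "freq_class", *DELETERIOUSNESS_FLAGS] + [f"af_{a}" for a in mix.labels]
        return pd.DataFrame(columns=cols)
    # restrict a configurable number of ultra-rare variants to AFR
    ur = table.index[table["freq_class"] == "ultra_rare"]
    for idx in ur[: spec.n_afr_only_ultra_rare]:
        for anc in mix.labels:
            if anc != "AFR":
                table.loc[idx, f"af_{anc}"] = 0.0
        # keep the AFR-only variants discoverable at desk-scale cohort sizes
        table.loc[idx, "af_AFR"] = np.nextafter(1e-4, 0)
    return table


def simulate_genotypes(
    variants: pd.DataFrame, cohort: pd.DataFrame, seed: int = 0
) -> np.ndarray:
    """0/1/2 ALT-dosage matrix, binomial Hardy-Weinberg draws within ancestry."""
    if len(cohort) == 0 or len(variants) == 0:
        raise ValueError("cohort and variant table must be non-empty")
    rng = np.random.default_rng(seed)
    anc = cohort["ancestry"].to_numpy()
    missing = [a for a in pd.unique(anc) if f"af_{a}" not in variants.columns]
    if missing:
        raise ValueError(f"cohort ancestries absent from variant AF table: {missing}")
    n, m = len(cohort), len(variants)
    G = np.empty((n, m), dtype=np.int8)
    af_cols = {a: variants[f"af_{a}"].to_numpy() for a in pd.unique(anc)}
    anc_idx = {a: np.where(anc == a)[0] for a in pd.unique(anc)}
    for a, idx in anc_idx.items():
        afs = af_cols[a]
        G[idx, :] = rng.binomial(2, afs[None, :], size=(len(idx), m)).astype(np.int8)
    return G


# ---------------------------------------------------------------------------
# traits and features
# ---------------------------------------------------------------------------

def qualifying_ultra_rare(variants: pd.DataFrame) -> pd.Series:
    """Ultra-rare PTVs and all-five-deleterious missense variants — the
    functional variant set through which planted gene effects act and which
    gene-level masks aggregate."""
    ptv = variants["consequence"].isin(
        {"transcript_ablation", "splice_acceptor", "splice_donor", "stop_gained", "frameshift"}
    )
    deleterious = np.ones(len(variants), dtype=bool)
    for f in DELETERIOUSNESS_FLAGS:
        deleterious &= variants[f].astype(bool).to_numpy()
    missense = (variants["consequence"] == "missense") & deleterious
    return (variants["freq_class"] == "ultra_rare") & (ptv | missense) & (variants["gene"] != "")


def _select_causal(variants: pd.DataFrame, cfg: EffectConfig, rng) -> tuple[dict, dict]:
    causal_v: dict[str, float] = {}
    for cls, k, beta in (
        ("common", cfg.n_causal_common, cfg.beta_common),
        ("rare", cfg.n_causal_rare, cfg.beta_rare),
    ):
        pool = variants.index[variants["freq_class"] == cls].to_numpy()
        if k and len(pool):
            pick = rng.choice(pool, size=min(k, len(pool)), replace=False)
            for i in pick:
                causal_v[variants.loc[i, "variant_id"]] = beta
    causal_g: dict[str, float] = {}
    if cfg.n_causal_genes:
        qual = variants[qualifying_ultra_rare(variants)]
        af_cols = [c for c in variants.columns if c.startswith("af_")]
        by_gene = qual.groupby("gene")[af_cols].sum().sum(axis=1).sort_values(ascending=False)
        for gene in by_gene.index[: cfg.n_causal_genes]:
            causal_g[str(gene)] = cfg.beta_gene
    return causal_v, causal_g


def simulate_traits(
    cohort: pd.DataFrame,
    genotypes: np.ndarray,
    variants: pd.DataFrame,
    cfg: EffectConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame, SimTruth]:
    """Latent log-PDFF, the observable feature panel, and the truth manifest.

    The latent trait is the sum of a feature-driven metabolic signal
    (standardized features times fixed signed loadings, scaled to
    ``feature_signal_sd``), the planted genetic effects, and Gaussian noise.
    Lab features are observed at a pre-imaging visit: their values decay
    toward independence with the participant's lab-to-imaging time gap, so
    time-gap weighting has something to recover.  Features other than the
    five required ones are masked completely at random at the configured
    missingness rate.
    """
    cfg = cfg or EffectConfig()
    if cfg.residual_sd <= 0:
        raise ValueError("residual SD must be positive")
    n = len(cohort)
    if genotypes.shape != (n, len(variants)):
        raise ValueError("genotype matrix does not match cohort x variants")
    rng = np.random.default_rng(seed)

    w = {name: w_f for name, _, _, w_f in FEATURE_PANEL}
    a = {name: a_f for name, _, a_f, _ in FEATURE_PANEL}
    # analytic SD of sum(w_f z_f): shared-factor part + independent parts
    var = (sum(w[f] * a[f] for f in w)) ** 2 + sum(
        w[f] ** 2 * (1 - a[f] ** 2) for f in w
    )
    scale = cfg.feature_signal_sd / math.sqrt(var)
    # latent-trait response to a unit shift of the metabolic factor
    s_m = scale * sum(w[f] * a[f] for f in w)

    causal_v, causal_g = _select_causal(variants, cfg, rng)
    vid_to_col = {v: j for j, v in enumerate(variants["variant_id"])}
    genetic = np.zeros(n)
    sex_mult = np.where(cohort["sex"].to_numpy() == 1, cfg.female_effect_multiplier, 1.0)
    for vid, beta in causal_v.items():
        genetic += beta * sex_mult * genotypes[:, vid_to_col[vid]]
    qual = qualifying_ultra_rare(variants)
    for gene, beta in causal_g.items():
        cols = [vid_to_col[v]
                for v in variants.loc[qual & (variants["gene"] == gene), "variant_id"]]
        burden = genotypes[:, cols].sum(axis=1)
        genetic += beta * sex_mult * burden
    # planted effects are deviations around the cohort mean so the trait
    # calibration does not drift with the effect configuration
    genetic -= genetic.mean()

    # route part of each effect through the metabolic factor (visible to the
    # feature panel), the rest hepatic-direct; total latent effect is beta
    share = cfg.upstream_effect_share if abs(s_m) > 1e-9 else 0.0
    M = rng.normal(0, 1, n) + (share / s_m) * genetic if share > 0 else rng.normal(0, 1, n)
    z = {}
    for name, _, a_f, _ in FEATURE_PANEL:
        z[name] = a_f * M + math.sqrt(1 - a_f**2) * rng.normal(0, 1, n)
    signal = scale * sum(w[f] * z[f] for f in w)

    latent = (
        cfg.intercept + signal + (1 - share) * genetic
        + rng.normal(0, cfg.residual_sd, n)
    )

    # observed features: liver-responsive labs reflect the realized trait
    # (genetics included), then drift with the lab-to-imaging gap
    downstream = latent - cfg.intercept - signal
    d_sd = downstream.std()
    D = downstream / d_sd if d_sd > 0 else np.zeros(n)
    gap = rng.uniform(0.0, cfg.time_gap_max_years, n)
    feats = {}
    for name, cat, a_f, _ in FEATURE_PANEL:
        v = z[name]
        if cat == "lab" and cfg.biomarker_feedback > 0:
            fb = cfg.biomarker_feedback * math.copysign(1.0, a_f)
            v = math.sqrt(1 - fb**2) * v + fb * D
        if cat == "lab" and cfg.lab_drift_per_year > 0:
            rho = np.exp(-cfg.lab_drift_per_year * gap)
            v = rho * v + np.sqrt(1 - rho**2) * rng.normal(0, 1, n)
        feats[name] = v
    features = pd.DataFrame(feats, index=cohort.index)
    # missing completely at random, required features always present
    for name in features.columns:
        if name in REQUIRED_FEATURES or cfg.feature_missing_rate <= 0:
            continue
        mask = rng.random(n) < cfg.feature_missing_rate
        features.loc[mask, name] = np.nan
    features["time_gap_years"] = gap
    features["age"] = cohort["age"].to_numpy()
    features["sex"] = cohort["sex"].to_numpy()
    features["fasting_time_h"] = cohort["fasting_time_h"].to_numpy()

    truth = SimTruth(
        seed=seed,
        causal_variants=causal_v,
        causal_genes=causal_g,
        latent_log_pdff=latent,
        true_steatosis=np.exp(latent) >= cfg.steatosis_threshold,
        feature_loadings={f: scale * w[f] for f in w},
        config=cfg,
    )
    return latent, features, truth


def simulate_observation(
    latent_log_pdff: np.ndarray,
    cohort: pd.DataFrame,
    cfg: EffectConfig | None = None,
    seed: int = 0,
    time_gap_years: np.ndarray | None = None,
) -> pd.DataFrame:
    """Observed phenotype table.

    True PDFF is revealed only in the imaging subsample.  ICD diagnosis is a
    Bernoulli(sensitivity) draw among true steatosis cases meeting the
    cardiometabolic criteria — never among non-cases unless the configured
    false-positive rate is raised — emulating clinical underdiagnosis.
    """
    cfg = cfg or EffectConfig()
    n = len(cohort)
    if len(latent_log_pdff) != n:
        raise ValueError("latent trait must cover every participant")
    rng = np.random.default_rng(seed)
    pdff = np.exp(np.asarray(latent_log_pdff, dtype=float))
    true_case = pdff >= cfg.steatosis_threshold
    imaging = rng.random(n) < cfg.imaging_fraction
    cardio_ok = rng.random(n) < cfg.cardiometabolic_rate
    exclusion = rng.random(n) < cfg.exclusionary_rate
    eligible = true_case & cardio_ok & ~exclusion
    diagnosed = eligible & (rng.random(n) < cfg.diagnosis_sensitivity)
    if cfg.false_positive_rate > 0:
        diagnosed |= ~true_case & (rng.random(n) < cfg.false_positive_rate)
    gap = (
        rng.uniform(0.0, cfg.time_gap_max_years, n)
        if time_gap_years is None
        else np.asarray(time_gap_years, dtype=float)
    )
    return pd.DataFrame(
        {
            "imaging": imaging,
            "true_pdff": np.where(imaging, pdff, np.nan),
            "true_steatosis": np.where(imaging, true_case, np.nan),
            "diagnosed_masld": diagnosed,
            "cardiometabolic_ok": cardio_ok,
            "exclusionary_dx": exclusion,
            "time_gap_years": gap,
        },
        index=cohort.index,
    )


# ---------------------------------------------------------------------------
# dataset bundle and writers
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    cohort: pd.DataFrame
    variants: pd.DataFrame
    genotypes: np.ndarray
    features: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: SimTruth


def simulate_dataset(
    n: int = 20000,
    mix: AncestryMix | None = None,
    spec: VariantSpec | None = None,
    cfg: EffectConfig | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Run every generator stage with sub-seeds derived from one seed."""
    ss = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    cohort = simulate_participants(n, mix, seed=seeds[0])
    variants = simulate_variants(spec, mix, seed=seeds[1])
    genotypes = simulate_genotypes(variants, cohort, seed=seeds[2])
    latent, features, truth = simulate_traits(cohort, genotypes, variants, cfg, seed=seeds[3])
    phenotypes = simulate_observation(
        latent, cohort, cfg, seed=seeds[3], time_gap_years=features["time_gap_years"].to_numpy()
    )
    return SimulatedDataset(cohort, variants, genotypes, features, phenotypes, truth)


def write_vcf(path: Path, variants: pd.DataFrame, genotypes: np.ndarray,
              sample_ids: list[str]) -> None:
    """Minimal VCF 4.2 writer: GT-only, one sample per participant, -1 = missing."""
    G = np.asarray(genotypes)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(variants["chrom"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        order = variants.sort_values(["chrom", "pos"]).index
        for i in order:
            v = variants.loc[i]
            col = variants.index.get_loc(i)
            gts = "\t".join(gt_strings[int(g)] for g in G[:, col])
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['variant_id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def write_dataset(data: SimulatedDataset, directory: str | Path) -> dict[str, Path]:
    """Write the full bundle: VCF genotypes, TSV tables, JSON truth manifest.

    Deterministic column order throughout; round-trips losslessly through
    the package's readers.
    """
    if len(data.cohort) == 0:
        raise ValueError("refusing to write an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "genotypes.vcf",
        "cohort": directory / "cohort.tsv",
        "features": directory / "features.tsv",
        "phenotypes": directory / "phenotypes.tsv",
        "variants": directory / "variants.tsv",
        "truth": directory / "truth.json",
    }
    write_vcf(paths["vcf"], data.variants, data.genotypes, list(data.cohort.index))
    data.cohort.to_csv(paths["cohort"], sep="\t")
    data.features.to_csv(paths["features"], sep="\t")
    data.phenotypes.to_csv(paths["phenotypes"], sep="\t")
    data.variants.to_csv(paths["variants"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(data.truth.to_json_dict(), fh, indent=2, sort_keys=True)
    return paths
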