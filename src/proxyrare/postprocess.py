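"""Post-processing of association results: replication against known variant
lists, genomic-inflation estimation, the post-hoc plausibility filter for
proxy-phenotype hits, and evidence tiering."""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from proxyrare.assoc import SignificanceThresholds

LIVER_ENZYMES = ("ALP", "ALT", "AST", "GGT")
METABOLIC_MARKERS = (
    "apoA",
    "apoB",
    "body_fat_pct",
    "cholesterol",
    "glucose",
    "HbA1c",
    "hip_circumference",
    "IGF1",
    "LpA",
    "SHBG",
    "triglycerides",
    "waist_circumference",
)


def significance_thresholds(n_genes_tested: int) -> SignificanceThresholds:
    """Study significance levels; the gene-level threshold is Bonferroni
    0.05 / number of genes tested."""
    if n_genes_tested < 1:
        raise ValueError("need at least one tested gene")
    return SignificanceThresholds(gene_bonferroni=0.05 / n_genes_tested)


def replication_score(
    results: pd.DataFrame,
    known: pd.DataFrame,
    alpha_gws: float = 5e-8,
    alpha_nominal: float = 0.05,
) -> dict:
    """Score replication of known associations.

    ``results`` indexed by variant id with columns p and beta (or z);
    ``known`` indexed by variant id with a ``direction`` column (+1/-1).
    Known variants absent from the results are counted as untested.

    Returns counts at both thresholds, the untested list, and a per-variant
    table with direction agreement.
    """
    if known.index.has_duplicates:
        raise ValueError("known-variant ids must be unique")
    rows = []
    untested = []
    for vid, row in known.iterrows():
        if vid not in results.index:
            untested.append(vid)
            continue
        res = results.loc[vid]
        eff = res["beta"] if "beta" in res and not pd.isna(res["beta"]) else res.get("z", np.nan)
        rows.append(
            {
                "variant_id": vid,
                "p": res["p"],
                "genome_wide": res["p"] < alpha_gws,
                "nominal": res["p"] < alpha_nominal,
                "direction_agrees": (
                    bool(np.sign(eff) == np.sign(row["direction"]))
                    if not pd.isna(eff)
                    else None
                ),
            }
        )
    table = pd.DataFrame(
        rows, columns=["variant_id", "p", "genome_wide", "nominal", "direction_agrees"]
    )
    return {
        "n_known": len(known),
        "n_tested": len(table),
        "n_untested": len(untested),
        "untested": untested,
        "n_genome_wide": int(table["genome_wide"].sum()) if len(table) else 0,
        "n_nominal": int(table["nominal"].sum()) if len(table) else 0,
        "table": table,
    }


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic inflation factor lambda_GC: the median association chi-square
    over its null median (the chi2_1 median, ~0.4549)."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if p.size < 100:
        warnings.warn(
            f"lambda_GC from only {p.size} p-values is noisy", stacklevel=2
        )
    chi2 = stats.chi2.isf(np.clip(p, 5e-324, 1.0), 1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, 1))


def posthoc_filter(
    hits: list[str],
    trait_pvalues: pd.DataFrame,
    liver_enzymes: tuple[str, ...] = LIVER_ENZYMES,
    metabolic_markers: tuple[str, ...] = METABOLIC_MARKERS,
    true_phenotypes: tuple[str, ...] = ("true_masld", "true_pdff"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Plausibility filter for proxy-phenotype hits.

    A hit is retained iff it is nominally associated with a true phenotype,
    OR with at least one liver enzyme AND at least two distinct metabolic
    dysfunction markers (all at two-sided p < alpha; no direction
    requirement).  ``trait_pvalues`` is hits x traits of nominal p-values.
    Unknown trait columns raise — the vocabularies are configuration.
    """
    vocab = set(liver_enzymes) | set(metabolic_markers) | set(true_phenotypes)
    unknown = [c for c in trait_pvalues.columns if c not in vocab]
    if unknown:
        raise ValueError(f"trait columns not in any configured vocabulary: {unknown}")
    rows = []
    for hit in hits:
        if hit not in trait_pvalues.index:
            rows.append({"target": hit, "retained": False, "reason": "no-trait-associations"})
            continue
        p = trait_pvalues.loc[hit]
        true_hit = any(
            t in p.index and not pd.isna(p[t]) and p[t] < alpha for t in true_phenotypes
        )
        n_liver = sum(
            1 for t in liver_enzymes if t in p.index and not pd.isna(p[t]) and p[t] < alpha
        )
        n_marker = sum(
            1 for t in metabolic_markers if t in p.index and not pd.isna(p[t]) and p[t] < alpha
        )
        if true_hit:
            rows.append({"target": hit, "retained": True, "reason": "true-phenotype-nominal"})
        elif n_liver >= 1 and n_marker >= 2:
            rows.append({"target": hit, "retained": True, "reason": "liver-and-metabolic"})
        else:
            rows.append(
                {
                    "target": hit,
                    "retained": False,
                    "reason": f"insufficient-support(liver={n_liver},markers={n_marker})",
                }
            )
    return pd.DataFrame(rows, columns=["target", "retained", "reason"]).set_index("target")


EVIDENCE_SOURCES = (
    "human_therapeutic",
    "monogenic_clinical",
    "animal_model",
    "differential_expression",
    "prior_genetic_association",
)


def evidence_tiering(evidence: pd.DataFrame) -> pd.Series:
    """Tier genes by count of supporting evidence sources.

    Tier 1: >= 4 sources; tier 2: exactly 3; tier 3: exactly 2; tier 4: <= 1.
    ``evidence`` is genes x the five boolean source columns.
    """
    missing = [c for c in EVIDENCE_SOURCES if c not in evidence.columns]
    if missing:
        raise ValueError(f"evidence table missing source columns: {missing}")
    counts = evidence[list(EVIDENCE_SOURCES)].astype(bool).sum(axis=1)
    tier = pd.Series(4, index=evidence.index, name="tier")
    tier[counts == 2] = 3
    tier[counts == 3] = 2
    tier[counts >= 4] = 1
    return tier
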