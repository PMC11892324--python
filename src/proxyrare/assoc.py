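"""Variant QC and rare-variant association testing.

Single variants are tested with ordinary least squares (quantitative traits)
or Firth-penalized logistic regression (binary traits, likelihood-ratio
p-values).  Gene-level tests aggregate ultra-rare variants (MAF < 1e-4) into
masks and apply BURDEN, SKAT, SKAT-O and ACAT.  Whole-genome block-ridge
regression supplies leave-one-chromosome-out (LOCO) polygenic offsets that
enter every downstream test as a fixed offset, guarding against proximal
contamination by polygenic background.

Conventions: coordinates are 1-based as in VCF, the effect allele is ALT and
dosages count ALT alleles.  MAC is min(alt count, ref count); MAF is computed
on non-missing dosages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

PTV_CONSEQUENCES = frozenset(
    {"transcript_ablation", "splice_acceptor", "splice_donor", "stop_gained", "frameshift"}
)
DELETERIOUSNESS_FLAGS = (
    "polyphen2_humvar",
    "polyphen2_humdiv",
    "sift",
    "lrt",
    "mutation_taster",
)

GENOME_WIDE_ALPHA = 5e-8
EXOME_WIDE_ALPHA = 4.3e-7


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value (conditional on allele counts).

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more probable than
    the observed one.

    Parameters are the three genotype counts.  Returns 1.0 for monomorphic
    sites (a single compatible configuration).
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers, got {counts}")
    n = int(n_hom_ref + n_het + n_hom_alt)
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_alt = 2 * int(n_hom_alt) + int(n_het)
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0
    # het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(het | allele counts) ~ multinomial with 2^het phasing factor
    from scipy.special import gammaln

    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * math.log(2.0)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = int(n_het)
    p_obs = prob[hets == obs]
    if p_obs.size == 0:
        raise ValueError("observed heterozygote count incompatible with allele counts")
    return float(min(1.0, prob[prob <= p_obs[0] * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCRules:
    """Thresholds for per-variant quality control.

    ``min_mac``/``mac_strict``: keep variants with MAC >= min_mac (or > if
    strict).  ``maf_min``/``maf_max`` bound MAF (inclusive lower, exclusive
    upper).  ``min_call_rate`` is strict (call rate must exceed it).
    ``hwe_p`` excludes variants whose HWE exact p falls below the threshold;
    ``hwe_literal`` inverts the rule to keep only variants below it.
    """

    min_mac: float = 0.0
    mac_strict: bool = False
    maf_min: float | None = None
    maf_max: float | None = None
    min_call_rate: float = 0.9
    hwe_p: float = 1e-15
    hwe_literal: bool = False

    @classmethod
    def step1(cls) -> "QCRules":
        """Whole-genome-model input filter: MAC > 100, MAF >= 0.01."""
        return cls(min_mac=100, mac_strict=True, maf_min=0.01)

    @classmethod
    def common_replication(cls) -> "QCRules":
        """Known-variant replication: MAF > 0.001."""
        return cls(maf_min=np.nextafter(0.001, 1))

    @classmethod
    def rare_single_variant(cls) -> "QCRules":
        """Rare/ultra-rare coding single-variant testing: MAC >= 10, MAF < 0.01."""
        return cls(min_mac=10, maf_max=0.01)


def variant_stats(dosages: np.ndarray) -> pd.DataFrame:
    """Per-variant call rate, AF, MAF, MAC and HWE p from an n x m dosage matrix.

    Missing genotypes are NaN and excluded from every denominator.
    """
    G = np.asarray(dosages, dtype=float)
    if G.ndim != 2:
        raise ValueError("dosage matrix must be 2-dimensional (participants x variants)")
    n = G.shape[0]
    miss = np.isnan(G)
    n_called = n - miss.sum(axis=0)
    alt = np.nansum(G, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = alt / (2.0 * n_called)
    maf = np.minimum(af, 1.0 - af)
    mac = np.minimum(alt, 2.0 * n_called - alt)
    hwe = np.ones(G.shape[1])
    for j in range(G.shape[1]):
        col = G[~miss[:, j], j]
        if col.size:
            hwe[j] = hwe_exact(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
    return pd.DataFrame(
        {
            "call_rate": n_called / n,
            "af": af,
            "maf": maf,
            "mac": mac,
            "hwe_p": hwe,
        }
    )


def variant_qc(
    dosages: np.ndarray, rules: QCRules, variant_ids: list[str] | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply QC rules; returns (boolean keep mask, per-variant report).

    The report records every rule outcome and the first failed rule per
    variant so dropped counts reconcile exactly.
    """
    report = variant_stats(dosages)
    if variant_ids is not None:
        report.index = pd.Index(variant_ids, name="variant_id")
    mac_ok = report["mac"] > rules.min_mac if rules.mac_strict else report["mac"] >= rules.min_mac
    maf_ok = pd.Series(True, index=report.index)
    if rules.maf_min is not None:
        maf_ok &= report["maf"] >= rules.maf_min
    if rules.maf_max is not None:
        maf_ok &= report["maf"] < rules.maf_max
    call_ok = report["call_rate"] > rules.min_call_rate
    hwe_ok = (
        report["hwe_p"] < rules.hwe_p if rules.hwe_literal else report["hwe_p"] >= rules.hwe_p
    )
    report["fail_mac"] = ~mac_ok
    report["fail_maf"] = ~maf_ok
    report["fail_call_rate"] = ~call_ok
    report["fail_hwe"] = ~hwe_ok
    keep = (mac_ok & maf_ok & call_ok & hwe_ok).to_numpy()
    fails = report[["fail_mac", "fail_maf", "fail_call_rate", "fail_hwe"]]
    report["failed_rule"] = fails.apply(
        lambda r: "" if not r.any() else r.index[r.argmax()].removeprefix("fail_"), axis=1
    )
    report["kept"] = keep
    return keep, report


# ---------------------------------------------------------------------------
# Association records
# ---------------------------------------------------------------------------

@dataclass
class AssociationRecord:
    """Result of one association test (variant- or gene-level)."""

    target: str
    trait: str = ""
    beta: float = math.nan
    se: float = math.nan
    z: float = math.nan
    p: float = math.nan
    n: int = 0
    cases: int | None = None
    controls: int | None = None
    af: float = math.nan
    mac: float = math.nan
    test: str = "linear"
    stratum: str = "pooled"
    flag: str = ""

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "trait": self.trait,
            "stratum": self.stratum,
            "n": self.n,
            "cases": self.cases,
            "controls": self.controls,
            "af": self.af,
            "mac": self.mac,
            "beta": self.beta,
            "se": self.se,
            "z": self.z,
            "p": self.p,
            "test": self.test,
            "flag": self.flag,
        }


# ---------------------------------------------------------------------------
# Linear / Firth single-variant tests
# ---------------------------------------------------------------------------

def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Covariate design matrix with an intercept prepended."""
    if covariates is None:
        return np.ones((n, 1))
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def _linear_test(g, y, X):
    """OLS of y on [X, g]; returns beta, se, t-based z, p."""
    n, k = X.shape
    D = np.column_stack([X, g])
    coef, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    dof = n - rank
    if dof <= 0:
        return math.nan, math.nan, math.nan, math.nan
    sigma2 = resid @ resid / dof
    XtX_inv = np.linalg.pinv(D.T @ D)
    se = math.sqrt(max(sigma2 * XtX_inv[-1, -1], 0.0))
    if se == 0:
        return float(coef[-1]), 0.0, math.nan, math.nan
    t = coef[-1] / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(coef[-1]), float(se), float(t), float(max(p, 5e-324))


def _firth_fit(D, y, offset=None, free=None, max_iter=100, tol=1e-6):
    """Firth-penalized logistic fit: Jeffreys-prior penalty, step-halving.

    ``free`` restricts optimization to a subset of coefficients (others
    pinned at 0) while the penalty keeps the FULL design's information
    determinant — the profile penalized likelihood needed for a calibrated
    penalized likelihood-ratio test.

    Returns (beta, cov, penalized log-likelihood, converged).
    """
    n, k = D.shape
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    free = np.ones(k, dtype=bool) if free is None else np.asarray(free, dtype=bool)
    beta = np.zeros(k)

    def penalized_ll(beta):
        eta = D @ beta + off
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        XtWX = (D * w[:, None]).T @ D
        sign, logdet = np.linalg.slogdet(XtWX)
        return ll + 0.5 * logdet if sign > 0 else -np.inf

    ll_old = penalized_ll(beta)
    converged = False
    cov = np.full((k, k), np.nan)
    for _ in range(max_iter):
        eta = D @ beta + off
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        XtWX = (D * w[:, None]).T @ D
        try:
            c, low = cho_factor(XtWX)
        except np.linalg.LinAlgError:
            break
        inv = cho_solve((c, low), np.eye(k))
        # hat-matrix diagonal of the full weighted design
        h = np.einsum("ij,jk,ik->i", D, inv, D) * w
        score = D.T @ (y - mu + h * (0.5 - mu))
        score_f = score[free]
        if np.linalg.norm(score_f) < tol:
            converged = True
            cov = inv
            break
        delta = np.zeros(k)
        sub = XtWX[np.ix_(free, free)]
        delta[free] = np.linalg.solve(sub, score_f)
        step = 1.0
        for _ in range(25):
            ll_new = penalized_ll(beta + step * delta)
            if ll_new >= ll_old - 1e-10:
                break
            step *= 0.5
        beta = beta + step * delta
        ll_old = penalized_ll(beta)
        cov = inv
    return beta, cov, penalized_ll(beta), converged


def single_variant_test(
    dosage: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    trait_type: str = "quantitative",
    target: str = "",
    trait_name: str = "",
    stratum: str = "pooled",
) -> AssociationRecord:
    """Test one variant against one trait.

    Quantitative traits: OLS with covariates, the LOCO offset subtracted from
    the phenotype.  Binary traits: Firth-penalized logistic regression with
    the offset in the linear predictor and a penalized likelihood-ratio
    p-value.  Monomorphic dosages and non-convergent fits produce flagged
    records rather than exceptions.
    """
    if trait_type not in ("quantitative", "binary"):
        raise ValueError(f"trait_type must be quantitative or binary, got {trait_type!r}")
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(trait, dtype=float)
    ok = ~np.isnan(g) & ~np.isnan(y)
    X = _design(covariates, len(g))
    if covariates is not None:
        ok &= ~np.isnan(np.asarray(covariates, dtype=float)).reshape(len(g), -1).any(axis=1)
    g, y, X = g[ok], y[ok], X[ok]
    off = None if offset is None else np.asarray(offset, dtype=float)[ok]
    n = len(g)
    alt = g.sum()
    af = alt / (2 * n) if n else math.nan
    mac = min(alt, 2 * n - alt)
    rec = AssociationRecord(
        target=target, trait=trait_name, n=n, af=af, mac=mac, stratum=stratum
    )
    if n == 0 or np.all(g == g[0]):
        rec.test = "none"
        rec.flag = "monomorphic"
        return rec
    if trait_type == "quantitative":
        y_adj = y if off is None else y - off
        beta, se, z, p = _linear_test(g, y_adj, X)
        rec.beta, rec.se, rec.z, rec.p = beta, se, z, p
        rec.test = "linear"
        return rec
    cases = int(y.sum())
    rec.cases, rec.controls = cases, n - cases
    rec.test = "firth"
    D1 = np.column_stack([X, g])
    free0 = np.ones(D1.shape[1], dtype=bool)
    free0[-1] = False  # null: genotype coefficient pinned at 0, full penalty
    b0, _, ll0, conv0 = _firth_fit(D1, y, offset=off, free=free0)
    b1, cov1, ll1, conv1 = _firth_fit(D1, y, offset=off)
    if not (conv0 and conv1):
        rec.flag = "non-convergence"
    beta = float(b1[-1])
    se = float(math.sqrt(max(cov1[-1, -1], 0.0))) if np.isfinite(cov1[-1, -1]) else math.nan
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    p = float(max(stats.chi2.sf(lrt, 1), 5e-324))
    z = math.copysign(math.sqrt(lrt), beta)
    rec.beta, rec.se, rec.z, rec.p = beta, se, z, p
    return rec


def association_scan(
    dosages: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    variant_ids: list[str] | None = None,
    trait_name: str = "",
) -> pd.DataFrame:
    """Vectorized OLS scan of many variants against a quantitative trait.

    Residualizes the trait and every dosage column on the covariates once,
    then tests each residualized variant marginally — algebraically identical
    to per-variant OLS with covariates.  Missing dosages are mean-imputed for
    the scan (single-variant follow-up drops them instead).
    """
    G = np.asarray(dosages, dtype=float)
    y = np.asarray(trait, dtype=float)
    if offset is not None:
        y = y - np.asarray(offset, dtype=float)
    n, m = G.shape
    X = _design(covariates, n)
    k = np.linalg.matrix_rank(X)
    af = np.nansum(G, axis=0) / (2.0 * (~np.isnan(G)).sum(axis=0))
    col_mean = np.nanmean(G, axis=0)
    idx = np.where(np.isnan(G))
    if idx[0].size:
        G = G.copy()
        G[idx] = np.take(col_mean, idx[1])
    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)
    gty = G_r.T @ y_r
    gtg = np.einsum("ij,ij->j", G_r, G_r)
    yty = y_r @ y_r
    dof = n - k - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = gty / gtg
        rss = yty - beta * gty
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / gtg)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    mono = gtg <= 1e-12
    out = pd.DataFrame(
        {
            "beta": np.where(mono, np.nan, beta),
            "se": np.where(mono, np.nan, se),
            "z": np.where(mono, np.nan, tstat),
            "p": np.where(mono, np.nan, np.maximum(p, 5e-324)),
            "n": n,
            "af": af,
            "mac": np.minimum(np.nansum(dosages, axis=0), 2 * n - np.nansum(dosages, axis=0)),
            "trait": trait_name,
        }
    )
    if variant_ids is not None:
        out.index = pd.Index(variant_ids, name="variant_id")
    return out


# ---------------------------------------------------------------------------
# Whole-genome block ridge with LOCO offsets
# ---------------------------------------------------------------------------

def ridge_loco(
    dosages: np.ndarray,
    chromosomes: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    block_size: int = 2000,
    alphas: tuple[float, ...] = (10.0, 100.0, 1000.0),
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-level block ridge regression with leave-one-chromosome-out offsets.

    Level 0: each block of up to ``block_size`` standardized variants yields
    cross-validated ridge predictions at every penalty in ``alphas``.  Level
    1: a ridge combination of the block predictions is refit once per
    chromosome using only blocks from the other chromosomes, so the offset
    for chromosome c never touches chromosome-c genotypes.

    Returns an n x n_chromosomes DataFrame of offsets (columns = chromosome
    labels) on the residualized-trait scale.
    """
    G = np.asarray(dosages, dtype=float)
    chroms = np.asarray(chromosomes)
    y = np.asarray(trait, dtype=float)
    labels = pd.unique(chroms)
    if len(labels) < 2:
        raise ValueError("LOCO offsets require variants on at least 2 chromosomes")
    n = len(y)
    X = _design(covariates, n)
    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)

    rng = np.random.default_rng(seed)
    fold = rng.integers(0, n_folds, size=n)

    preds, block_chrom = [], []
    for c in labels:
        cols = np.where(chroms == c)[0]
        for start in range(0, len(cols), block_size):
            block = G[:, cols[start : start + block_size]]
            mu = np.nanmean(block, axis=0)
            sd = np.nanstd(block, axis=0)
            sd[sd == 0] = 1.0
            Z = (np.where(np.isnan(block), mu, block) - mu) / sd
            Z = Z - Q @ (Q.T @ Z)
            for alpha in alphas:
                pred = np.empty(n)
                for f in range(n_folds):
                    tr, te = fold != f, fold == f
                    Zt = Z[tr]
                    A = Zt.T @ Zt + alpha * np.eye(Z.shape[1])
                    w = np.linalg.solve(A, Zt.T @ y_r[tr])
                    pred[te] = Z[te] @ w
                preds.append(pred)
                block_chrom.append(c)
    P = np.column_stack(preds)
    block_chrom = np.asarray(block_chrom)

    offsets = {}
    lam = 1.0
    for c in labels:
        keep = block_chrom != c
        Pk = P[:, keep]
        A = Pk.T @ Pk + lam * np.eye(Pk.shape[1])
        w = np.linalg.solve(A, Pk.T @ y_r)
        offsets[str(c)] = Pk @ w
    return pd.DataFrame(offsets)


# ---------------------------------------------------------------------------
# Gene masks
# ---------------------------------------------------------------------------

@dataclass
class GeneMask:
    """Ultra-rare variant aggregation unit for gene-level testing."""

    gene: str
    variant_ids: list[str]
    mask_class: str  # "ptv" or "ptv_deleterious_missense"
    cumulative_mac: float


def build_masks(
    variants: pd.DataFrame,
    dosages: np.ndarray,
    mask_class: str = "ptv_deleterious_missense",
    maf_max: float = 1e-4,
    min_cumulative_mac: float = 10,
) -> tuple[list[GeneMask], pd.DataFrame]:
    """Build per-gene ultra-rare variant masks.

    ``variants`` needs columns: variant_id, gene, consequence, and the five
    deleteriousness flag columns.  PTVs always qualify; missense variants
    qualify for the combined mask only when flagged deleterious by all five
    predictors.  MAF/MAC are computed from the dosage matrix.  Genes whose
    qualifying variants sum to cumulative MAC < ``min_cumulative_mac`` are
    dropped with a logged reason.

    Returns (masks, drop log).
    """
    if mask_class not in ("ptv", "ptv_deleterious_missense"):
        raise ValueError(f"unknown mask class {mask_class!r}")
    st = variant_stats(dosages)
    st.index = variants.index
    is_ptv = variants["consequence"].isin(PTV_CONSEQUENCES)
    deleterious = np.ones(len(variants), dtype=bool)
    for flag in DELETERIOUSNESS_FLAGS:
        deleterious &= variants[flag].astype(bool).to_numpy()
    is_missense = (variants["consequence"] == "missense").to_numpy()
    qualifies = is_ptv.to_numpy().copy()
    if mask_class == "ptv_deleterious_missense":
        qualifies |= is_missense & deleterious
    qualifies &= (st["maf"] < maf_max).to_numpy()
    qualifies &= variants["gene"].notna().to_numpy() & (variants["gene"] != "").to_numpy()

    masks, dropped = [], []
    sub = variants.loc[qualifies].copy()
    sub["mac"] = st.loc[qualifies, "mac"].to_numpy()
    for gene, grp in sub.groupby("gene", sort=True):
        cmac = float(grp["mac"].sum())
        if cmac < min_cumulative_mac:
            dropped.append({"gene": gene, "cumulative_mac": cmac, "reason": "cmac_below_min"})
            continue
        masks.append(
            GeneMask(
                gene=str(gene),
                variant_ids=list(grp["variant_id"]),
                mask_class=mask_class,
                cumulative_mac=cmac,
            )
        )
    return masks, pd.DataFrame(dropped, columns=["gene", "cumulative_mac", "reason"])


# ---------------------------------------------------------------------------
# Mixture-of-chi-squares p-values (SKAT machinery)
# ---------------------------------------------------------------------------

def _liu_params(lambdas: np.ndarray):
    """Liu et al. moment-matching parameters for sum(lambda_j chi2_1)."""
    lam = np.asarray(lambdas, dtype=float)
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    mu_q = c1
    sigma_q = math.sqrt(2 * c2)
    if s1**2 > s2:
        a = 1 / (s1 - math.sqrt(s1**2 - s2))
        d = s1 * a**3 - a**2
        l = a**2 - 2 * d
    else:
        l = 1 / s2
        a = math.sqrt(l)
        d = 0.0
    return mu_q, sigma_q, l, d


def _liu_sf_vec(q: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Vectorized Liu survival function for a fixed mixture."""
    mu_q, sigma_q, l, d = _liu_params(lambdas)
    mu_x = l + d
    sigma_x = math.sqrt(2 * (l + 2 * d))
    t = (np.asarray(q, dtype=float) - mu_q) / sigma_q * sigma_x + mu_x
    return stats.ncx2.sf(t, l, d) if d > 0 else stats.chi2.sf(t, l)


def _liu_pvalue(q: float, lambdas: np.ndarray) -> float:
    mu_q, sigma_q, l, d = _liu_params(lambdas)
    mu_x = l + d
    sigma_x = math.sqrt(2 * (l + 2 * d))
    t = (q - mu_q) / sigma_q * sigma_x + mu_x
    return float(stats.ncx2.sf(t, l, d) if d > 0 else stats.chi2.sf(t, l))


def _imhof_pvalue(q: float, lambdas: np.ndarray) -> float:
    """Numerical inversion of the characteristic function (Imhof's method)."""
    lam = np.asarray(lambdas, dtype=float)

    def integrand(u):
        theta = 0.5 * float(np.sum(np.arctan(lam * u))) - 0.5 * q * u
        log_rho = 0.25 * float(np.sum(np.log1p((lam * u) ** 2)))
        return math.sin(theta) / (u * math.exp(log_rho))

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0, np.inf, limit=1000, epsabs=1e-12)
    return float(min(max(0.5 + val / math.pi, 5e-324), 1.0))


def chi2_mixture_pvalue(q: float, lambdas: np.ndarray, refine_below: float = 1e-4) -> float:
    """P(sum_j lambda_j chi2_1 > q): Liu moment matching with an Imhof
    numerical-inversion refinement in the tail.

    A single eigenvalue is handled exactly.  The inversion integral loses
    precision past p ~ 1e-10 (cancellation against the 0.5 constant), so
    results below that are left to the moment-matching approximation.
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > max(1e-10 * lam.max(initial=0.0), 0.0)]
    if lam.size == 0:
        return 1.0
    if lam.size == 1:
        return float(min(max(stats.chi2.sf(q / lam[0], 1), 5e-324), 1.0))
    p = _liu_pvalue(q, lam)
    if p < refine_below:
        p_ref = _imhof_pvalue(q, lam)
        if p_ref > 1e-10:
            p = p_ref
    return float(min(max(p, 5e-324), 1.0))


def _beta_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    return stats.beta.pdf(np.clip(maf, 1e-12, 1 - 1e-12), a, b)


def _null_model(y, X, offset, trait_type):
    """Null-model residuals and per-individual variances for score tests."""
    if trait_type == "quantitative":
        y_adj = y if offset is None else y - offset
        Q, _ = np.linalg.qr(X)
        resid = y_adj - Q @ (Q.T @ y_adj)
        dof = len(y) - X.shape[1]
        sigma2 = resid @ resid / dof
        v = np.full(len(y), sigma2)
        return resid, v
    # binary: standard logistic null MLE (score-test convention)
    beta, _, _, _ = _firth_fit(X, y, offset=offset)
    eta = X @ beta + (0 if offset is None else offset)
    mu = expit(eta)
    return y - mu, np.clip(mu * (1 - mu), 1e-12, None)


def _adjusted_genotypes(G, X, v):
    """Project weighted genotypes off the covariates in the v-metric."""
    Xv = X * v[:, None]
    XtVX_inv = np.linalg.pinv(X.T @ Xv)
    return G - X @ (XtVX_inv @ (Xv.T @ G))


def skat_test(G, y, X, offset=None, trait_type="quantitative", weights=None):
    """SKAT variance-component score test; returns (Q, p, lambdas)."""
    resid, v = _null_model(y, X, offset, trait_type)
    if weights is None:
        af = G.sum(axis=0) / (2 * G.shape[0])
        weights = _beta_weights(np.minimum(af, 1 - af))
    W = np.asarray(weights, dtype=float)
    score = (G * W).T @ resid
    if trait_type == "quantitative":
        sigma2 = v[0]
        Q = float(score @ score) / sigma2
        Gt = _adjusted_genotypes(G * W, X, np.ones(len(y)))
        K = Gt.T @ Gt
    else:
        Q = float(score @ score)
        Gt = _adjusted_genotypes(G * W, X, v)
        K = (G * W).T @ (Gt * v[:, None])
    lam = np.linalg.eigvalsh((K + K.T) / 2)
    lam = lam[lam > 1e-10 * max(lam.max(initial=0.0), 1.0)]
    p = chi2_mixture_pvalue(Q, lam)
    return Q, p, lam


def acat_combine(pvalues: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Cauchy combination of p-values: robust to dependence.

    T = sum w_j tan((0.5-p_j) pi) / sum w_j; p = 0.5 - arctan(T)/pi.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        return math.nan
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)[: len(p)]
    p = np.minimum(p, 1 - 1e-16)
    tiny = p < 1e-16
    terms = np.where(tiny, 1.0 / (p * math.pi), np.tan((0.5 - p) * math.pi))
    T = float(np.sum(w * terms) / np.sum(w))
    if T > 1e15:
        return float(max(1.0 / (T * math.pi), 5e-324))
    return float(min(max(0.5 - math.atan(T) / math.pi, 5e-324), 1.0))


def _skato_pvalue(G, y, X, offset, trait_type, weights, rho_grid):
    """Lee et al. optimal unified SKAT-burden test over a rho grid.

    Q(rho) = score' R_rho score with R_rho = (1-rho)I + rho 11'.  The minimum
    p over the grid is corrected via the shared one-dimensional decomposition
    Q(rho) ~ (1-rho) kappa + tau(rho) chi2_1, integrating over the common
    chi2_1 component.
    """
    resid, v = _null_model(y, X, offset, trait_type)
    W = np.asarray(weights, dtype=float)
    m = G.shape[1]
    score = (G * W).T @ resid
    if trait_type == "quantitative":
        sigma2 = v[0]
        scale = sigma2
        Zh = _adjusted_genotypes(G * W, X, np.ones(len(y)))
    else:
        scale = 1.0
        Zh = _adjusted_genotypes(G * W, X, v) * np.sqrt(v)[:, None]
    # Zh' Zh = Var(score)/scale, so Q(rho)/scale ~ sum eig(K R_rho) chi2_1
    K = Zh.T @ Zh

    p_rho, lam_rho, Qs = {}, {}, {}
    for rho in rho_grid:
        R = (1 - rho) * np.eye(m) + rho * np.ones((m, m))
        Qs[rho] = float(score @ R @ score) / scale
        lam = np.real(np.linalg.eigvals(K @ R))
        lam = np.sort(lam[lam > 1e-10 * max(lam.max(initial=0.0), 1.0)])[::-1]
        if lam.size == 0:
            lam = np.array([1e-12])
        lam_rho[rho] = lam
        p_rho[rho] = chi2_mixture_pvalue(Qs[rho], lam)
    T = min(p_rho.values())
    if m == 1 or len(rho_grid) == 1:
        return T, p_rho

    zbar = Zh.mean(axis=1)
    zbar2 = float(zbar @ zbar)
    if zbar2 < 1e-300:
        return float(min(1.0, T * len(rho_grid))), p_rho
    cof = (zbar @ Zh) / zbar2
    Z2 = Zh - np.outer(zbar, cof)
    lam_kappa = np.linalg.eigvalsh(Z2.T @ Z2)
    lam_kappa = lam_kappa[lam_kappa > 1e-10 * max(lam_kappa.max(initial=0.0), 1.0)]
    if lam_kappa.size == 0:
        return float(min(1.0, T * len(rho_grid))), p_rho
    mu_q = float(lam_kappa.sum())
    var_remain = 4.0 * float(np.sum((np.outer(zbar, cof).T @ Z2) ** 2))
    var_q = 2.0 * float(np.sum(lam_kappa**2)) + var_remain
    tau = np.array(
        [m**2 * rho * zbar2 + (1 - rho) * float(np.sum(cof**2)) * zbar2 for rho in rho_grid]
    )

    # q_min(rho): null quantile of each Q(rho) at 1-T via the Liu inverse
    qmin = np.empty(len(rho_grid))
    for i, rho in enumerate(rho_grid):
        mu, sig, l, _ = _liu_params(lam_rho[rho])
        q_org = stats.chi2.ppf(max(1 - T, 5e-324), l)
        qmin[i] = (q_org - l) / math.sqrt(2 * l) * sig + mu

    rhos = np.minimum(np.asarray(rho_grid, dtype=float), 0.999)
    lam_sum = float(lam_kappa.sum())
    var_shrink = math.sqrt(max(var_q - var_remain, 1e-300)) / math.sqrt(var_q)

    # integrate over the shared chi2_1 component on Gauss-Legendre nodes
    nodes, wts = np.polynomial.legendre.leggauss(128)
    x = 20.0 * (nodes + 1.0)  # map [-1,1] -> [0,40]
    wts = wts * 20.0
    mv = np.min((qmin[:, None] - np.outer(tau, x)) / (1 - rhos[:, None]), axis=0)
    adj = (mv - mu_q) * var_shrink + mu_q
    surv = _liu_sf_vec(adj, lam_kappa)
    surv = np.where(mv <= 0, 1.0, np.where(mv > lam_sum * 1e4, 0.0, surv))
    dens = np.exp(-x / 2) / np.sqrt(2 * math.pi * x)  # chi2_1 pdf
    val = float(np.sum((1.0 - surv) * dens * wts))
    p = float(min(max(1.0 - val, T), min(1.0, T * len(rho_grid))))
    return p, p_rho


SKATO_RHO_GRID = tuple([0.0] + [round(r**2, 4) for r in np.arange(0.1, 1.0, 0.1)] + [1.0])


def gene_test(
    mask: GeneMask,
    dosages: np.ndarray,
    variant_index: dict[str, int],
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    trait_type: str = "quantitative",
    method: str = "burden",
    trait_name: str = "",
    stratum: str = "pooled",
    burden_weights: np.ndarray | None = None,
    skat_weights: np.ndarray | None = None,
    min_cumulative_mac: float = 10,
) -> AssociationRecord:
    """Gene-level association test of a mask's aggregated ultra-rare variants.

    method: "burden" collapses to a weighted dosage sum and reports an effect
    size; "skat", "skato" report score-test p-values without beta/SE; "acat"
    Cauchy-combines per-variant p-values.
    """
    method = method.lower()
    if method not in ("burden", "skat", "skato", "acat"):
        raise ValueError(f"unknown gene-level method {method!r}")
    target = f"{mask.gene}:{mask.mask_class}:{method}"
    if mask.cumulative_mac < min_cumulative_mac:
        return AssociationRecord(
            target=target, trait=trait_name, test=method, stratum=stratum,
            flag="cmac_below_min", mac=mask.cumulative_mac,
        )
    cols = [variant_index[v] for v in mask.variant_ids]
    G = np.asarray(dosages, dtype=float)[:, cols]
    G = np.where(np.isnan(G), 0.0, G)
    y = np.asarray(trait, dtype=float)
    X = _design(covariates, len(y))
    if method == "burden":
        w = np.ones(G.shape[1]) if burden_weights is None else np.asarray(burden_weights)
        rec = single_variant_test(
            G @ w, y, covariates=covariates, offset=offset, trait_type=trait_type,
            target=target, trait_name=trait_name, stratum=stratum,
        )
        rec.test = "burden" if rec.test != "none" else rec.test
        rec.mac = mask.cumulative_mac
        return rec
    if method == "acat":
        ps = []
        for j in range(G.shape[1]):
            r = single_variant_test(
                G[:, j], y, covariates=covariates, offset=offset, trait_type=trait_type
            )
            if not math.isnan(r.p):
                ps.append(r.p)
        p = acat_combine(np.array(ps)) if ps else math.nan
        rec = AssociationRecord(
            target=target, trait=trait_name, p=p, n=len(y), mac=mask.cumulative_mac,
            test="acat", stratum=stratum, flag="" if ps else "no_testable_variants",
        )
        return rec
    af = G.sum(axis=0) / (2 * G.shape[0])
    weights = (
        _beta_weights(np.minimum(af, 1 - af)) if skat_weights is None else np.asarray(skat_weights)
    )
    if method == "skat":
        Q, p, _ = skat_test(G, y, X, offset=offset, trait_type=trait_type, weights=weights)
        return AssociationRecord(
            target=target, trait=trait_name, p=p, n=len(y), mac=mask.cumulative_mac,
            test="skat", stratum=stratum,
        )
    p, _ = _skato_pvalue(G, y, X, offset, trait_type, weights, list(SKATO_RHO_GRID))
    return AssociationRecord(
        target=target, trait=trait_name, p=p, n=len(y), mac=mask.cumulative_mac,
        test="skato", stratum=stratum,
    )


# ---------------------------------------------------------------------------
# PVE and power
# ---------------------------------------------------------------------------

def pve(beta: float, se: float, maf: float, n: float) -> float:
    """Proportion of phenotypic variance explained by a single variant.

    PVE = 2 b^2 MAF(1-MAF) / [2 b^2 MAF(1-MAF) + SE^2 2N MAF(1-MAF)],
    which simplifies to b^2 / (b^2 + N SE^2) — the MAF terms cancel.
    """
    if se <= 0:
        raise ValueError("SE must be positive")
    if n <= 0:
        raise ValueError("N must be positive")
    if not 0 < maf <= 0.5:
        raise ValueError("MAF must lie in (0, 0.5]")
    num = 2 * beta**2 * maf * (1 - maf)
    return float(num / (num + se**2 * 2 * n * maf * (1 - maf)))


def power_from_pve(pve_value: float, n: float, alpha: float = 0.05, attenuation: float = 1.0) -> float:
    """Power of a 1-df association test at a given explained-variance fraction.

    Proxy phenotypes attenuate the signal by the squared predicted-true
    correlation (``attenuation``); true phenotypes use attenuation 1.  The
    test statistic is noncentral chi-square with lambda = n q/(1-q) for
    q = pve * attenuation.
    """
    if not 0 <= pve_value < 1:
        raise ValueError("pve must lie in [0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    q = pve_value * attenuation
    if q >= 1:
        raise ValueError("pve * attenuation must be < 1")
    lam = n * q / (1 - q)
    crit = stats.chi2.ppf(1 - alpha, 1)
    return float(stats.ncx2.sf(crit, 1, lam)) if lam > 0 else float(alpha)


@dataclass(frozen=True)
class SignificanceThresholds:
    """Study-wide significance levels."""

    genome_wide: float = GENOME_WIDE_ALPHA
    exome_wide: float = EXOME_WIDE_ALPHA
    gene_bonferroni: float = 0.05 / 18520
    nominal: float = 0.05
    rescue_mac_min: float = 5
    rescue_mac_max: float = 10  # exclusive
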