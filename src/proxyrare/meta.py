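"""Trans-ancestral meta-analysis of association records.

The primary combination is a sample-size-and-direction-of-effect analysis
(Stouffer's weighted Z with weights sqrt(N_eff)), chosen over a standard
SE-based analysis because cohort effect sizes are on different scales
(quantitative liver-fat vs. binary case-control cohorts of varying
prevalence) and because score/LRT-based cohort p-values make Z differ
slightly from beta/SE.  An inverse-variance-weighted meta-analysis is run
alongside for effect-size bookkeeping, and Cochran's Q quantifies
heterogeneity (flagged at p < 0.10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

HETEROGENEITY_ALPHA = 0.10


def effective_n(trait_type: str, n: float | None = None, cases: float | None = None,
                controls: float | None = None) -> float:
    """Effective sample size: N for quantitative traits, 4/(1/cases + 1/controls)
    for binary traits (the equivalent balanced-design N)."""
    if trait_type == "quantitative":
        if n is None or n <= 0:
            raise ValueError("quantitative traits need a positive n")
        return float(n)
    if trait_type == "binary":
        if not cases or not controls or cases <= 0 or controls <= 0:
            raise ValueError("binary traits need positive case and control counts")
        return float(4.0 / (1.0 / cases + 1.0 / controls))
    raise ValueError(f"unknown trait_type {trait_type!r}")


@dataclass
class CohortResult:
    """One cohort's contribution to a meta-analysis."""

    cohort: str
    z: float | None = None
    p: float | None = None
    direction: int = 0  # +1 / -1 / 0 (unknown)
    n_eff: float = math.nan
    beta: float | None = None
    se: float | None = None
    ref: str | None = None
    alt: str | None = None

    def signed_z(self) -> float:
        """Z signed by the cohort effect direction; recovered from p when
        only (p, direction) are reported (score/LRT cohorts)."""
        if self.z is not None and not math.isnan(self.z):
            return float(self.z)
        if self.p is None or math.isnan(self.p):
            raise ValueError(f"cohort {self.cohort}: neither z nor p available")
        mag = -stats.norm.ppf(max(self.p, 5e-324) / 2.0)
        sign = self.direction if self.direction != 0 else (
            0 if self.beta is None else (1 if self.beta > 0 else -1)
        )
        if sign == 0:
            raise ValueError(f"cohort {self.cohort}: direction unknown, cannot sign Z")
        return float(sign * mag)


@dataclass
class MetaRecord:
    """Meta-analysis output for one target."""

    target: str
    z: float
    p: float
    direction: str
    n_eff_total: float
    q: float = math.nan
    df: int = 0
    p_het: float = math.nan
    het_flag: bool = False
    beta_ivw: float = math.nan
    se_ivw: float = math.nan
    p_ivw: float = math.nan
    stratum_level: str = "pooled"

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "stratum_level": self.stratum_level,
            "z": self.z,
            "p": self.p,
            "direction": self.direction,
            "q": self.q,
            "df": self.df,
            "p_het": self.p_het,
            "het_flag": self.het_flag,
            "beta_ivw": self.beta_ivw,
            "se_ivw": self.se_ivw,
            "n_eff_total": self.n_eff_total,
        }


def _check_alleles(records: list[CohortResult]) -> None:
    pairs = {(r.ref, r.alt) for r in records if r.ref is not None and r.alt is not None}
    if len(pairs) > 1:
        raise ValueError(
            f"effect-allele mismatch across cohorts: {sorted(pairs)}; align alleles "
            "explicitly before meta-analysis (no silent flipping)"
        )


def stouffer_meta(records: list[CohortResult], target: str = "",
                  stratum_level: str = "pooled") -> MetaRecord:
    """Sample-size-weighted Z meta-analysis.

    Z_meta = sum(w_k Z_k) / sqrt(sum(w_k^2)) with w_k = sqrt(N_eff,k); the
    two-sided p comes from the normal tail.  The direction string records
    each cohort's effect sign (+/-/?) in input order.
    """
    if not records:
        raise ValueError("at least one cohort record required")
    _check_alleles(records)
    zs = np.array([r.signed_z() for r in records])
    w = np.sqrt(np.array([r.n_eff for r in records]))
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("every cohort needs a positive effective sample size")
    z_meta = float(np.sum(w * zs) / math.sqrt(np.sum(w**2)))
    p = float(max(2.0 * stats.norm.sf(abs(z_meta)), 5e-324))
    direction = "".join("+" if z > 0 else "-" if z < 0 else "?" for z in zs)
    rec = MetaRecord(
        target=target, z=z_meta, p=p, direction=direction,
        n_eff_total=float(np.sum([r.n_eff for r in records])),
        stratum_level=stratum_level,
    )
    if len(records) >= 2 and all(
        r.beta is not None and r.se is not None and r.se > 0 for r in records
    ):
        rec.q, rec.df, rec.p_het = cochran_q(records)
        rec.het_flag = rec.p_het < HETEROGENEITY_ALPHA
        b, s, p_ivw = ivw_meta(records)
        rec.beta_ivw, rec.se_ivw, rec.p_ivw = b, s, p_ivw
    return rec


def ivw_meta(records: list[CohortResult]) -> tuple[float, float, float]:
    """Inverse-variance-weighted effect-size meta-analysis -> (beta, se, p)."""
    if not records:
        raise ValueError("at least one cohort record required")
    for r in records:
        if r.beta is None or r.se is None or not r.se > 0:
            raise ValueError(f"cohort {r.cohort}: beta and positive se required for IVW")
    betas = np.array([r.beta for r in records])
    w = np.array([1.0 / r.se**2 for r in records])
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    p = float(max(2.0 * stats.norm.sf(abs(beta / se)), 5e-324))
    return beta, se, p


def cochran_q(records: list[CohortResult]) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test -> (Q, df, p_het)."""
    if len(records) < 2:
        raise ValueError("heterogeneity needs at least 2 cohorts")
    beta_meta, _, _ = ivw_meta(records)
    q = float(sum((r.beta - beta_meta) ** 2 / r.se**2 for r in records))
    df = len(records) - 1
    p_het = float(stats.chi2.sf(q, df))
    return q, df, max(p_het, 5e-324)


def stratified_meta(
    records_by_stratum: dict[str, list[CohortResult]], target: str = ""
) -> tuple[dict[str, MetaRecord], MetaRecord, list[str]]:
    """Two-level meta-analysis across strata (ancestries or sexes).

    Each stratum's cohort records are combined by Stouffer; the stratum-level
    results are then combined again (meta-meta), with stratum heterogeneity
    quantified by Cochran's Q on stratum-level estimates where effect sizes
    are available.  Strata with no testable records are omitted and logged.

    Returns (per-stratum records, combined record, omitted-stratum log).
    """
    per_stratum: dict[str, MetaRecord] = {}
    omitted: list[str] = []
    stratum_level_inputs: list[CohortResult] = []
    for stratum, recs in records_by_stratum.items():
        usable = [r for r in recs if r.n_eff > 0 and not math.isnan(r.n_eff)]
        if not usable:
            omitted.append(f"stratum {stratum}: no testable records")
            continue
        mr = stouffer_meta(usable, target=target, stratum_level=stratum)
        per_stratum[stratum] = mr
        stratum_level_inputs.append(
            CohortResult(
                cohort=stratum, z=mr.z, n_eff=mr.n_eff_total,
                beta=mr.beta_ivw if not math.isnan(mr.beta_ivw) else None,
                se=mr.se_ivw if not math.isnan(mr.se_ivw) else None,
            )
        )
    if not stratum_level_inputs:
        raise ValueError("no stratum had testable records")
    combined = stouffer_meta(stratum_level_inputs, target=target, stratum_level="meta")
    return per_stratum, combined, omitted


def meta_table(records: list[MetaRecord]) -> pd.DataFrame:
    """Meta-results as a TSV-ready DataFrame."""
    return pd.DataFrame([r.to_dict() for r in records])
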