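"""Phenotype construction: true and predicted MASLD status, threshold
performance tables, and rank-based inverse-normal transformation.

MASLD case-control definitions mirror EHR consensus practice: cases are
diagnosed participants meeting cardiometabolic criteria without exclusionary
diagnoses; gray-zone and overlap exclusions are recorded with reasons, never
silently dropped, so every downstream N reconciles with its inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CASE = "case"
CONTROL = "control"
EXCLUDED = "excluded"

REASON_EXCLUSIONARY = "exclusionary-diagnosis"
REASON_CARDIOMETABOLIC = "cardiometabolic-fail"
REASON_GRAY_ZONE = "gray-zone"
REASON_OVERLAP = "overlap-removed"


@dataclass(frozen=True)
class MasldStatus:
    participant_id: str
    status: str  # case | control | excluded
    reason: str = ""

    def __post_init__(self):
        if self.status == EXCLUDED and not self.reason:
            raise ValueError("excluded participants must carry a reason")


def _status_frame(statuses: list[MasldStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.participant_id, s.status, s.reason) for s in statuses],
        columns=["participant_id", "status", "reason"],
    ).set_index("participant_id")


def define_true_masld(
    diagnosed: pd.Series,
    cardiometabolic_ok: pd.Series,
    exclusionary: pd.Series,
    overlap_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Diagnosis-based MASLD status for every participant.

    ``diagnosed``, ``cardiometabolic_ok`` and ``exclusionary`` are boolean
    Series indexed by participant id over the same cohort.  Cases are
    diagnosed participants meeting cardiometabolic criteria without
    exclusionary diagnoses; controls are undiagnosed participants without
    exclusionary diagnoses; exclusions carry reasons.  Participants in
    ``overlap_ids`` (e.g. the imaging subsample, removed to avoid sample
    overlap in meta-analysis) are excluded entirely.
    """
    idx = diagnosed.index
    for name, s in (("cardiometabolic_ok", cardiometabolic_ok), ("exclusionary", exclusionary)):
        if not s.index.equals(idx):
            raise ValueError(f"{name} index does not match the diagnosis table")
    overlap_ids = overlap_ids or set()
    unknown = overlap_ids - set(idx)
    statuses = []
    for pid in idx:
        if pid in overlap_ids:
            statuses.append(MasldStatus(pid, EXCLUDED, REASON_OVERLAP))
        elif exclusionary.loc[pid]:
            statuses.append(MasldStatus(pid, EXCLUDED, REASON_EXCLUSIONARY))
        elif diagnosed.loc[pid]:
            if cardiometabolic_ok.loc[pid]:
                statuses.append(MasldStatus(pid, CASE))
            else:
                statuses.append(MasldStatus(pid, EXCLUDED, REASON_CARDIOMETABOLIC))
        else:
            statuses.append(MasldStatus(pid, CONTROL))
    out = _status_frame(statuses)
    out.attrs["overlap_ids_not_in_cohort"] = sorted(unknown)
    return out


def assign_predicted_status(
    predicted_pdff: pd.Series,
    cardiometabolic_ok: pd.Series,
    lower: float = 4.0,
    upper: float = 6.0,
) -> pd.DataFrame:
    """Predicted MASLD status from predicted PDFF (% units).

    <= ``lower`` -> predicted control; >= ``upper`` and cardiometabolic
    criteria met -> predicted case; >= ``upper`` without criteria ->
    excluded; strictly between the thresholds -> excluded (gray zone, kept
    out to protect predictive values at both ends).
    """
    if not lower < upper:
        raise ValueError(f"thresholds inverted: lower={lower} >= upper={upper}")
    statuses = []
    for pid, val in predicted_pdff.items():
        if math.isnan(val):
            statuses.append(MasldStatus(pid, EXCLUDED, "missing-prediction"))
        elif val <= lower:
            statuses.append(MasldStatus(pid, CONTROL))
        elif val >= upper:
            if bool(cardiometabolic_ok.get(pid, False)):
                statuses.append(MasldStatus(pid, CASE))
            else:
                statuses.append(MasldStatus(pid, EXCLUDED, REASON_CARDIOMETABOLIC))
        else:
            statuses.append(MasldStatus(pid, EXCLUDED, REASON_GRAY_ZONE))
    return _status_frame(statuses)


def threshold_performance(
    predicted_pdff: pd.Series,
    steatosis: pd.Series,
    thresholds: np.ndarray | list[float],
) -> pd.DataFrame:
    """PPV/NPV/sensitivity/specificity of thresholded predicted PDFF.

    ``steatosis`` is the dichotomized truth (PDFF >= 5.5%) on the overlap of
    both Series.  One row per threshold; empty denominators yield NaN rates
    with the zero counts reported.
    """
    common = predicted_pdff.index.intersection(steatosis.index)
    if len(common) == 0:
        raise ValueError("no overlap between predictions and truth")
    pred = predicted_pdff.loc[common].to_numpy(dtype=float)
    truth = steatosis.loc[common].to_numpy(dtype=bool)
    rows = []
    for thr in thresholds:
        above = pred >= thr
        tp = int(np.sum(above & truth))
        fp = int(np.sum(above & ~truth))
        fn = int(np.sum(~above & truth))
        tn = int(np.sum(~above & ~truth))
        rows.append(
            {
                "threshold": thr,
                "n_above": tp + fp,
                "n_below": tn + fn,
                "ppv": tp / (tp + fp) if tp + fp else math.nan,
                "npv": tn / (tn + fn) if tn + fn else math.nan,
                "sensitivity": tp / (tp + fn) if tp + fn else math.nan,
                "specificity": tn / (tn + fp) if tn + fp else math.nan,
            }
        )
    return pd.DataFrame(rows)


def rank_inverse_normal(values: np.ndarray, k: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transformation (Blom offset by default).

    x_i -> Phi^{-1}((rank_i - k) / (n - 2k + 1)) with midranks for ties.
    NaNs are preserved and excluded from ranking.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    v = x[ok]
    if v.size < 2 or np.all(v == v[0]):
        raise ValueError("rank-INT needs at least 2 distinct finite values")
    ranks = stats.rankdata(v, method="average")
    out[ok] = stats.norm.ppf((ranks - k) / (v.size - 2 * k + 1))
    return out
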