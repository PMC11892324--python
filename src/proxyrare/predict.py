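"""Weighted nested-CV prediction of log liver fat (log-PDFF) from a
feature panel.

The estimator trains k_outer x k_inner gradient-boosted tree models over a
nested fold partition: each outer fold serves as a holdout set once, and
within the remaining folds each inner fold serves as a validation set once.
Per-participant predictions average only the models whose training and
validation sets never contained that participant, so cohort-wide predictions
are leakage-free by construction and the bookkeeping is exhaustively
auditable from the membership records.

Participants measured long before imaging carry weaker label information;
training weights are inversely proportional to the lab-to-imaging time gap,
floored at 5: w_i = max(5, g_max / g_i).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

TIME_GAP_COLUMN = "time_gap_years"


def inclusion_filter(
    features: pd.DataFrame,
    countable_columns: list[str],
    required_columns: tuple[str, ...] = ("bmi", "waist_circumference", "alt", "ast", "triglycerides"),
    min_present: int = 38,
) -> pd.Index:
    """Participants eligible for model training.

    Eligibility requires (a) at least ``min_present`` non-missing values
    among the countable laboratory/physical columns and (b) every required
    column present.  Deterministic.
    """
    missing_cols = [c for c in required_columns if c not in features.columns]
    if missing_cols:
        raise ValueError(f"required feature columns absent: {missing_cols}")
    bad = [c for c in countable_columns if c not in features.columns]
    if bad:
        raise ValueError(f"countable columns absent from the matrix: {bad}")
    n_present = features[countable_columns].notna().sum(axis=1)
    required_ok = features[list(required_columns)].notna().all(axis=1)
    return features.index[(n_present >= min_present) & required_ok]


def compute_weights(time_gaps: np.ndarray, mode: str = "floor") -> np.ndarray:
    """Training weights from lab-to-imaging gaps: w_i = max(5, g_max / g_i).

    The printed formula floors weights at 5 (mode="floor"); mode="cap"
    exposes the alternative reading min(5, g_max/g_i).  Zero gaps take the
    ratio of the smallest positive gap so baseline-visit rows stay finite.
    """
    g = np.asarray(time_gaps, dtype=float)
    if np.any(g < 0):
        raise ValueError("time gaps must be non-negative")
    g = g.copy()
    if np.any(g == 0):
        positive = g[g > 0]
        if positive.size == 0:
            return np.full(g.shape, 5.0)
        g[g == 0] = positive.min()
    ratio = g.max() / g
    if mode == "floor":
        return np.maximum(5.0, ratio)
    if mode == "cap":
        return np.minimum(5.0, ratio)
    raise ValueError(f"unknown weight mode {mode!r}")


def _engine_params(n_train: int, overrides: dict | None) -> dict:
    """Gradient-boosting settings, scaled down automatically for small n."""
    params = {
        "n_estimators": int(max(10, min(750, 5 * n_train / 100))),
        "learning_rate": 0.01,
        "num_leaves": 60,
        "min_child_samples": min(100, max(5, n_train // 20)),
        "data_sample_strategy": "goss",
        "verbose": -1,
    }
    if overrides:
        params.update(overrides)
    return params


@dataclass
class ModelMembership:
    """Which participants each model saw, by row id."""

    outer_fold: int
    inner_fold: int
    train_ids: frozenset
    valid_ids: frozenset
    holdout_ids: frozenset


class NestedCVRegressor(BaseEstimator, RegressorMixin):
    """Nested cross-validated gradient-boosted regressor with leakage-free
    prediction averaging.

    Parameters
    ----------
    k_outer, k_inner : int
        Fold counts of the nested scheme (k_outer x k_inner models).
    seed : int
        Controls the fold partition and the engine.
    engine_params : dict or None
        Overrides for the boosting engine (missing values are handled
        natively; the loss is weighted squared error).
    weight_mode : str
        "floor" (printed formula) or "cap".

    Attributes
    ----------
    models_ : list of fitted boosters.
    membership_ : list of ModelMembership, one per model.
    holdout_prediction_ : Series of honest per-participant holdout
        predictions (each participant predicted only by models that held
        its outer fold out).
    feature_names_ : list of training columns.
    """

    def __init__(self, k_outer: int = 10, k_inner: int = 10, seed: int = 0,
                 engine_params: dict | None = None, weight_mode: str = "floor"):
        self.k_outer = k_outer
        self.k_inner = k_inner
        self.seed = seed
        self.engine_params = engine_params
        self.weight_mode = weight_mode

    def fit(self, X: pd.DataFrame, y, time_gaps=None, sample_weight=None):
        """Fit k_outer x k_inner models.

        ``X`` must be a DataFrame indexed by participant id (ids drive the
        leakage bookkeeping).  ``time_gaps`` derives weights via the
        max(5, g_max/g) formula when ``sample_weight`` is not given.
        """
        if self.k_outer < 2 or self.k_inner < 2:
            raise ValueError("fold counts must be at least 2")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame indexed by participant id")
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")
        if sample_weight is None:
            sample_weight = (
                compute_weights(np.asarray(time_gaps, float), self.weight_mode)
                if time_gaps is not None
                else np.ones(len(y))
            )
        ids = X.index.to_numpy()
        self.feature_names_ = list(X.columns)
        Xv = X.reset_index(drop=True)

        outer = KFold(n_splits=self.k_outer, shuffle=True, random_state=self.seed)
        self.models_ = []
        self.membership_ = []
        holdout_pred = {}
        for o, (rest_idx, hold_idx) in enumerate(outer.split(Xv)):
            inner = KFold(
                n_splits=self.k_inner, shuffle=True, random_state=self.seed + 1 + o
            )
            fold_preds = []
            for i, (tr_sub, va_sub) in enumerate(inner.split(rest_idx)):
                tr_idx = rest_idx[tr_sub]
                va_idx = rest_idx[va_sub]
                params = _engine_params(len(tr_idx), self.engine_params)
                model = lgb.LGBMRegressor(random_state=self.seed + 100 * o + i, **params)
                model.fit(
                    Xv.iloc[tr_idx], y[tr_idx], sample_weight=sample_weight[tr_idx],
                    eval_set=[(Xv.iloc[va_idx], y[va_idx])],
                    eval_sample_weight=[sample_weight[va_idx]],
                    callbacks=[lgb.early_stopping(25, verbose=False)],
                )
                self.models_.append(model)
                self.membership_.append(
                    ModelMembership(
                        outer_fold=o, inner_fold=i,
                        train_ids=frozenset(ids[tr_idx]),
                        valid_ids=frozenset(ids[va_idx]),
                        holdout_ids=frozenset(ids[hold_idx]),
                    )
                )
                fold_preds.append(model.predict(Xv.iloc[hold_idx]))
            for j, idx in enumerate(hold_idx):
                holdout_pred[ids[idx]] = float(np.mean([fp[j] for fp in fold_preds]))
        self.holdout_prediction_ = pd.Series(holdout_pred, name="holdout_prediction")
        self.n_models_ = len(self.models_)
        return self

    def _contributing(self, pids: np.ndarray) -> np.ndarray:
        """Boolean (n x n_models) matrix: model never saw the participant."""
        seen = [m.train_ids | m.valid_ids for m in self.membership_]
        out = np.ones((len(pids), len(seen)), dtype=bool)
        for k, s in enumerate(seen):
            out[:, k] = [pid not in s for pid in pids]
        return out

    def predict_table(self, X: pd.DataFrame, timepoint: str = "imaging") -> pd.DataFrame:
        """Leakage-aware averaged predictions with provenance.

        Returns a frame (participant_id index): prediction, n_models,
        timepoint.  Baseline predictions force the time-gap covariate to 0.
        Participants seen by every model get n_models = 0 and a NaN
        prediction, flagged rather than silently averaged.
        """
        check_is_fitted(self, "models_")
        if timepoint not in ("imaging", "baseline"):
            raise ValueError("timepoint must be 'imaging' or 'baseline'")
        Xp = X[self.feature_names_].copy()
        if timepoint == "baseline" and TIME_GAP_COLUMN in Xp.columns:
            Xp[TIME_GAP_COLUMN] = 0.0
        preds = np.column_stack([m.predict(Xp) for m in self.models_])
        keep = self._contributing(Xp.index.to_numpy())
        n_models = keep.sum(axis=1)
        with np.errstate(invalid="ignore"):
            avg = np.where(
                n_models > 0, (preds * keep).sum(axis=1) / np.maximum(n_models, 1), np.nan
            )
        return pd.DataFrame(
            {"prediction": avg, "n_models": n_models, "timepoint": timepoint},
            index=Xp.index,
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_table(X)["prediction"].to_numpy()

    def save(self, directory: str | Path) -> None:
        """Persist boosters plus a JSON manifest of memberships and config."""
        check_is_fitted(self, "models_")
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.models_):
            m.booster_.save_model(str(d / f"model_{i:03d}.txt"))
        manifest = {
            "k_outer": self.k_outer,
            "k_inner": self.k_inner,
            "seed": self.seed,
            "engine_params": self.engine_params,
            "feature_names": self.feature_names_,
            "membership": [
                {
                    "outer_fold": m.outer_fold,
                    "inner_fold": m.inner_fold,
                    "train_ids": sorted(m.train_ids),
                    "valid_ids": sorted(m.valid_ids),
                    "holdout_ids": sorted(m.holdout_ids),
                }
                for m in self.membership_
            ],
        }
        with open(d / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)


def evaluate_predictions(
    predictions: pd.Series,
    true_pdff: pd.Series,
    steatosis_threshold: float = 5.5,
    n_bootstrap: int = 1000,
    seed: int = 0,
    subgroup: pd.Index | None = None,
) -> dict:
    """Prediction accuracy against measured PDFF.

    Computes Pearson r and R^2 (1 - SS_res/SS_tot) between predicted and
    true log-PDFF, plus AUROC/AUPRC for identifying steatosis
    (PDFF >= threshold) from the predicted score, with percentile-bootstrap
    95% CIs.  ``subgroup`` restricts the evaluation (e.g. time-gap strata).
    Constant predictions leave r undefined (NaN) rather than erroring.
    """
    common = predictions.index.intersection(true_pdff.dropna().index)
    if subgroup is not None:
        common = common.intersection(subgroup)
    if len(common) == 0:
        raise ValueError("no overlap between predictions and measured PDFF")
    pred = predictions.loc[common].to_numpy(dtype=float)
    truth_log = np.log(true_pdff.loc[common].to_numpy(dtype=float))
    label = true_pdff.loc[common].to_numpy(dtype=float) >= steatosis_threshold

    def metrics(p, t_log, lab):
        out = {}
        if np.std(p) == 0 or np.std(t_log) == 0:
            out["r"] = math.nan
        else:
            out["r"] = float(stats.pearsonr(p, t_log)[0])
        ss_res = float(np.sum((t_log - p) ** 2))
        ss_tot = float(np.sum((t_log - t_log.mean()) ** 2))
        out["r2"] = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
        if 0 < lab.sum() < len(lab):
            out["auroc"] = float(roc_auc_score(lab, p))
            out["auprc"] = float(average_precision_score(lab, p))
        else:
            out["auroc"] = math.nan
            out["auprc"] = math.nan
        return out

    point = metrics(pred, truth_log, label)
    rng = np.random.default_rng(seed)
    boots = {k: [] for k in point}
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(pred), len(pred))
        bm = metrics(pred[idx], truth_log[idx], label[idx])
        for k, v in bm.items():
            boots[k].append(v)
    out = {"n": len(common), **point}
    for k, vals in boots.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size:
            out[f"{k}_ci"] = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
        else:
            out[f"{k}_ci"] = (math.nan, math.nan)
    return out


def feature_attribution(model: NestedCVRegressor, X: pd.DataFrame) -> pd.DataFrame:
    """Signed per-feature attribution ranking.

    Uses the trees' additive local attributions (efficiency holds: per-model
    attributions sum to prediction minus baseline), averaged over the
    ensemble.  The sign is Spearman's rho between feature values and
    attributions; features are ranked by mean absolute attribution.
    """
    check_is_fitted(model, "models_")
    Xf = X[model.feature_names_]
    Xv = Xf.to_numpy(dtype=float)
    contribs = np.zeros((len(X), len(model.feature_names_)))
    baseline = 0.0
    for m in model.models_:
        c = m.predict(Xf, pred_contrib=True)
        contribs += c[:, :-1]
        baseline += float(c[0, -1])
    contribs /= len(model.models_)
    baseline /= len(model.models_)
    rows = []
    for j, name in enumerate(model.feature_names_):
        col = Xv[:, j]
        attr = contribs[:, j]
        ok = ~np.isnan(col)
        if ok.sum() > 2 and np.std(attr[ok]) > 0 and np.std(col[ok]) > 0:
            rho = float(stats.spearmanr(col[ok], attr[ok])[0])
        else:
            rho = math.nan
        rows.append(
            {"feature": name, "mean_abs_attribution": float(np.mean(np.abs(attr))), "sign": rho}
        )
    out = pd.DataFrame(rows).sort_values(
        "mean_abs_attribution", ascending=False, ignore_index=True
    )
    out.attrs["baseline"] = baseline
    out.attrs["contributions"] = contribs
    return out
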