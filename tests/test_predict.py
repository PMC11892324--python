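"""Predictor tests: inclusion rules, time-gap weighting, nested-CV fold
bookkeeping and leakage, evaluation metrics, and attribution."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proxyrare import simulate as sim
from proxyrare.predict import (
    NestedCVRegressor,
    compute_weights,
    evaluate_predictions,
    feature_attribution,
    inclusion_filter,
)

FAST_ENGINE = {"n_estimators": 40, "min_child_samples": 5, "num_leaves": 15}


class TestInclusionFilter:
    @pytest.fixture()
    def panel(self):
        rng = np.random.default_rng(0)
        cols = [f"lab{i}" for i in range(70)] + ["bmi", "waist_circumference", "alt",
                                                 "ast", "triglycerides"]
        df = pd.DataFrame(rng.normal(size=(4, 75)), columns=cols,
                          index=[f"P{i}" for i in range(4)])
        # P1: missing bmi but 74/75 present
        df.loc["P1", "bmi"] = np.nan
        # P2: exactly 38 of 75 present incl. the required five
        df.loc["P2", [f"lab{i}" for i in range(33, 70)]] = np.nan
        # P3: only 10 measurements
        df.loc["P3", [f"lab{i}" for i in range(5, 70)]] = np.nan
        return df, cols

    def test_complete_participant_included(self, panel):
        df, cols = panel
        assert "P0" in inclusion_filter(df, cols)

    def test_missing_required_feature_excludes_despite_74_of_75(self, panel):
        df, cols = panel
        assert "P1" not in inclusion_filter(df, cols)

    def test_exactly_38_of_75_is_included(self, panel):
        df, cols = panel
        assert df.loc["P2", cols].notna().sum() == 38
        assert "P2" in inclusion_filter(df, cols)
        assert "P3" not in inclusion_filter(df, cols)

    def test_absent_required_column_errors(self, panel):
        df, cols = panel
        with pytest.raises(ValueError, match="required"):
            inclusion_filter(df.drop(columns=["bmi"]), [c for c in cols if c != "bmi"])


class TestWeights:
    def test_equal_gaps_all_floor_at_five(self):
        assert np.all(compute_weights(np.full(10, 3.0)) == 5.0)

    @pytest.mark.parametrize("gap,expected", [(0.5, 20.0), (4.0, 5.0), (10.0, 5.0)])
    def test_printed_formula_arithmetic(self, gap, expected):
        w = compute_weights(np.array([10.0, gap]))
        assert w[1] == expected

    def test_zero_gap_uses_smallest_positive_gap(self):
        w = compute_weights(np.array([0.0, 2.0, 10.0]))
        assert w[0] == w[1] == 5.0

    def test_cap_mode_and_negative_gap(self):
        assert np.all(compute_weights(np.array([10.0, 1.0]), mode="cap") == np.array([1.0, 5.0]))
        with pytest.raises(ValueError):
            compute_weights(np.array([-1.0]))

    def test_weights_non_increasing_in_gap(self, rng):
        g = np.sort(rng.uniform(0.1, 14, 50))
        w = compute_weights(g)
        assert np.all(np.diff(w) <= 1e-12)
        assert w.min() == 5.0


def _toy_xy(n=300, seed=0, n_features=6):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, n_features)),
        columns=[f"f{j}" for j in range(n_features)],
        index=[f"P{i:05d}" for i in range(n)],
    )
    y = 1.2 * X["f0"].to_numpy() - 0.8 * X["f1"].to_numpy() + rng.normal(0, 0.5, n)
    return X, y


class TestNestedCV:
    def test_10x10_scheme_yields_100_models(self):
        X, y = _toy_xy(n=600, seed=1)
        m = NestedCVRegressor(k_outer=10, k_inner=10, seed=1, engine_params=FAST_ENGINE)
        m.fit(X, y)
        assert m.n_models_ == 100

    def test_2x2_scheme_partitions_participants(self):
        X, y = _toy_xy(n=200, seed=2)
        m = NestedCVRegressor(k_outer=2, k_inner=2, seed=2, engine_params=FAST_ENGINE)
        m.fit(X, y)
        assert m.n_models_ == 4
        holdout_count = {pid: 0 for pid in X.index}
        for mm in m.membership_:
            assert not (mm.train_ids & mm.valid_ids)
            assert not (mm.train_ids & mm.holdout_ids)
            assert not (mm.valid_ids & mm.holdout_ids)
            assert mm.train_ids | mm.valid_ids | mm.holdout_ids == set(X.index)
        outer_holdouts = {mm.outer_fold: mm.holdout_ids for mm in m.membership_}
        for pid in X.index:
            n_folds_holding = sum(pid in h for h in outer_holdouts.values())
            assert n_folds_holding == 1

    def test_cohort_member_contributions_equal_k_inner(self):
        X, y = _toy_xy(n=240, seed=3)
        m = NestedCVRegressor(k_outer=3, k_inner=4, seed=3, engine_params=FAST_ENGINE)
        m.fit(X, y)
        table = m.predict_table(X)
        assert (table["n_models"] == 4).all()
        # no contributing model ever saw the participant
        for pid in X.index[:20]:
            for mm, model_seen in zip(
                m.membership_, [mm.train_ids | mm.valid_ids for mm in m.membership_]
            ):
                if pid not in model_seen:
                    assert pid in mm.holdout_ids

    def test_unseen_participants_use_all_models(self):
        X, y = _toy_xy(n=200, seed=4)
        m = NestedCVRegressor(k_outer=2, k_inner=2, seed=4, engine_params=FAST_ENGINE)
        m.fit(X, y)
        X_new, _ = _toy_xy(n=10, seed=99)
        X_new.index = [f"N{i}" for i in range(10)]
        table = m.predict_table(X_new)
        assert (table["n_models"] == 4).all()
        assert table["prediction"].notna().all()

    def test_shuffled_labels_destroy_holdout_correlation(self):
        X, y = _toy_xy(n=400, seed=5)
        m = NestedCVRegressor(k_outer=2, k_inner=2, seed=5, engine_params=FAST_ENGINE)
        m.fit(X, y)
        r_signal = stats.pearsonr(
            m.holdout_prediction_.loc[X.index].to_numpy(), y
        )[0]
        rng = np.random.default_rng(5)
        r_perm = []
        for _ in range(20):
            yp = rng.permutation(y)
            mp = NestedCVRegressor(k_outer=2, k_inner=2, seed=5, engine_params=FAST_ENGINE)
            mp.fit(X, yp)
            r_perm.append(stats.pearsonr(mp.holdout_prediction_.loc[X.index].to_numpy(), yp)[0])
        # signal beats every permuted fit (rank test, p = 1/21 < 0.05)
        assert r_signal > max(r_perm)
        assert abs(np.mean(r_perm)) < 0.2

    def test_baseline_timepoint_zeroes_time_gap(self):
        X, y = _toy_xy(n=200, seed=6)
        X["time_gap_years"] = np.random.default_rng(6).uniform(0, 14, len(X))
        m = NestedCVRegressor(k_outer=2, k_inner=2, seed=6, engine_params=FAST_ENGINE)
        m.fit(X, y)
        X0 = X.copy()
        X0["time_gap_years"] = 0.0
        np.testing.assert_allclose(
            m.predict_table(X, timepoint="baseline")["prediction"],
            m.predict_table(X0, timepoint="imaging")["prediction"],
        )


class TestEvaluate:
    def test_perfect_predictions(self):
        rng = np.random.default_rng(0)
        pdff = pd.Series(np.exp(rng.normal(1.05, 0.8, 500)),
                         index=[f"P{i}" for i in range(500)])
        pred = pd.Series(np.log(pdff.to_numpy()), index=pdff.index)
        ev = evaluate_predictions(pred, pdff, n_bootstrap=50)
        assert ev["r"] == pytest.approx(1.0)
        assert ev["r2"] == pytest.approx(1.0)
        assert ev["auroc"] == pytest.approx(1.0)

    def test_anticorrelated_score_gives_auroc_below_half(self):
        rng = np.random.default_rng(1)
        pdff = pd.Series(np.exp(rng.normal(1.05, 0.8, 500)),
                         index=[f"P{i}" for i in range(500)])
        pred = pd.Series(-np.log(pdff.to_numpy()), index=pdff.index)
        ev = evaluate_predictions(pred, pdff, n_bootstrap=0)
        assert ev["auroc"] < 0.5

    def test_random_predictions_auroc_near_half(self):
        rng = np.random.default_rng(2)
        n = 10_000
        pdff = pd.Series(np.exp(rng.normal(1.05, 0.8, n)), index=range(n))
        pred = pd.Series(rng.normal(size=n), index=pdff.index)
        ev = evaluate_predictions(pred, pdff, n_bootstrap=0)
        n1 = int((pdff >= 5.5).sum())
        n0 = n - n1
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(ev["auroc"] - 0.5) < 4 * se

    def test_constant_predictions_report_nan_r(self):
        pdff = pd.Series([2.0, 6.0, 3.0, 8.0], index=list("abcd"))
        pred = pd.Series([1.0, 1.0, 1.0, 1.0], index=pdff.index)
        ev = evaluate_predictions(pred, pdff, n_bootstrap=0)
        assert np.isnan(ev["r"])


class TestAttribution:
    def test_efficiency_and_noise_feature_ranked_last(self):
        rng = np.random.default_rng(3)
        n = 400
        X = pd.DataFrame(
            {"driver": rng.normal(size=n), "helper": rng.normal(size=n),
             "noise": rng.normal(size=n)},
            index=[f"P{i}" for i in range(n)],
        )
        y = 2.0 * X["driver"].to_numpy() + 0.5 * X["helper"].to_numpy() + rng.normal(0, 0.3, n)
        m = NestedCVRegressor(k_outer=2, k_inner=2, seed=3, engine_params=FAST_ENGINE)
        m.fit(X, y)
        attr = feature_attribution(m, X)
        assert list(attr["feature"]) == ["driver", "helper", "noise"]
        assert attr.loc[attr["feature"] == "driver", "sign"].iloc[0] > 0
        # efficiency: attributions + baseline reproduce the all-model mean prediction
        contribs = attr.attrs["contributions"]
        mean_pred = np.mean([mm.predict(X) for mm in m.models_], axis=0)
        np.testing.assert_allclose(
            contribs.sum(axis=1) + attr.attrs["baseline"], mean_pred, atol=1e-6
        )

    def test_negative_loading_feature_gets_negative_sign(self):
        # SHBG-analogue: negatively loaded on the latent trait
        data = sim.simulate_dataset(
            n=2500,
            spec=sim.VariantSpec(n_common=5, n_rare=5, n_ultra_rare=5, n_genes=2,
                                 n_afr_only_ultra_rare=0),
            seed=13,
        )
        cols = [n for n, _, _, _ in sim.FEATURE_PANEL]
        X = data.features[cols]
        y = data.truth.latent_log_pdff
        m = NestedCVRegressor(k_outer=2, k_inner=2, seed=13, engine_params=FAST_ENGINE)
        m.fit(X, y)
        attr = feature_attribution(m, X).set_index("feature")
        assert attr.loc["shbg", "sign"] < 0
        assert attr.loc["bmi", "sign"] > 0
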