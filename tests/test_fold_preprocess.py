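"""Leakage-control layer: fold plans, chained RF imputation,
standardization/encoding, and the midpoint SMOTE scheme."""

import joblib
import numpy as np
import pandas as pd
import pytest

from memiselect import make_fold_plan, rf_impute_fit, smote_rebalance, standardize_and_encode


class TestFoldPlan:
    def test_partition_sizes_and_coverage_at_n191(self):
        labels = (np.arange(191) % 5 == 0).astype(int)
        plan = make_fold_plan(labels, n_outer=10, n_repeats=2, seed=0)
        for r in range(2):
            sizes = np.bincount(plan.assignments[r])
            assert set(sizes) <= {19, 20} and sizes.sum() == 191

    def test_determinism_and_seed_sensitivity(self):
        labels = (np.arange(100) % 3 == 0).astype(int)
        a = make_fold_plan(labels, seed=7).assignments
        b = make_fold_plan(labels, seed=7).assignments
        c = make_fold_plan(labels, seed=8).assignments
        assert np.array_equal(a, b) and not np.array_equal(a, c)
        # repeats within one plan use distinct partitions
        assert not np.array_equal(a[0], a[1])

    def test_stratification_spreads_positives_evenly(self):
        labels = np.zeros(191, dtype=int)
        labels[:30] = 1
        plan = make_fold_plan(labels, n_outer=10, n_repeats=3, seed=1)
        for r in range(3):
            pos = [labels[plan.assignments[r] == f].sum() for f in range(10)]
            assert min(pos) >= 2 and max(pos) <= 4  # 3 +/- 1

    def test_too_few_positives_raises_actionable_error(self):
        labels = np.zeros(50, dtype=int)
        labels[:4] = 1
        with pytest.raises(ValueError, match="fewer"):
            make_fold_plan(labels, n_outer=10)


def _toy_frame(n=60, seed=0, missing=None):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "x1": rng.normal(10, 2, n),
            "x2": rng.normal(-3, 5, n),
            "flag": rng.integers(0, 2, n),
            "color": rng.choice(["red", "green", "blue", "grey"], n),
        }
    )
    if missing:
        for col, idx in missing.items():
            df[col] = df[col].astype(object if col == "color" else float)
            df.loc[idx, col] = np.nan
    return df


class TestImputation:
    def test_constant_column_imputes_the_constant(self):
        df = _toy_frame(40, seed=1)
        df["x1"] = 7.0
        df.loc[5, "x1"] = np.nan
        state = rf_impute_fit(df, seed=0)
        out = standardize_and_encode(state, df)
        # constant column has sd 0 -> transform leaves centred zeros; the
        # imputed cell equals the constant in state units
        assert state.means["x1"] == pytest.approx(7.0)
        assert out["x1"].abs().max() == 0.0

    def test_complete_data_is_identity(self):
        df = _toy_frame(50, seed=2)
        state = rf_impute_fit(df, seed=0)
        out = standardize_and_encode(state, df)
        back = out["x1"] * state.sds["x1"] + state.means["x1"]
        assert np.allclose(back, df["x1"])
        assert state.n_passes == 0

    def test_observed_cells_never_altered(self):
        df = _toy_frame(80, seed=3, missing={"x1": [1, 5, 9], "color": [2, 7]})
        state = rf_impute_fit(df, seed=0)
        out = standardize_and_encode(state, df)
        obs = df["x1"].notna()
        back = out.loc[obs, "x1"] * state.sds["x1"] + state.means["x1"]
        assert np.allclose(back, df.loc[obs, "x1"])

    def test_forest_beats_mean_imputation_on_correlated_data(self):
        rng = np.random.default_rng(4)
        n = 300
        z = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "a": z + 0.2 * rng.normal(size=n),
                "b": 2 * z + 0.2 * rng.normal(size=n),
                "c": -z + 0.2 * rng.normal(size=n),
            }
        )
        truth = df.copy()
        mask = rng.random((n, 3)) < 0.10
        df = df.mask(pd.DataFrame(mask, columns=df.columns))
        state = rf_impute_fit(df, seed=0, max_iter=5)
        out = standardize_and_encode(state, df)
        rmse_rf, rmse_mean = [], []
        for col in df.columns:
            miss = df[col].isna()
            imputed = out.loc[miss, col] * state.sds[col] + state.means[col]
            rmse_rf.append(np.sqrt(((imputed - truth.loc[miss, col]) ** 2).mean()))
            col_mean = df[col].mean()
            rmse_mean.append(np.sqrt(((col_mean - truth.loc[miss, col]) ** 2).mean()))
        assert np.mean(rmse_rf) < np.mean(rmse_mean)

    def test_fully_missing_column_rejected(self):
        df = _toy_frame(20, seed=5)
        df["x1"] = np.nan
        with pytest.raises(ValueError):
            rf_impute_fit(df, seed=0)


class TestStandardizeEncode:
    def test_training_columns_become_mean0_sd1(self, trial200):
        P = trial200.predictors()
        state = rf_impute_fit(P, seed=1, max_iter=2, n_estimators=20)
        X = standardize_and_encode(state, P)
        for col in ("age", "gad_severity", "self_compassion"):
            assert abs(X[col].mean()) < 1e-9
            assert abs(X[col].std(ddof=0) - 1) < 1e-9

    def test_value_at_training_mean_maps_to_zero(self):
        df = _toy_frame(50, seed=6)
        state = rf_impute_fit(df, seed=0)
        probe = df.iloc[[0]].copy()
        probe["x1"] = state.means["x1"]
        assert standardize_and_encode(state, probe)["x1"].iloc[0] == 0.0

    def test_four_level_one_hot_sums_to_one(self, trial200):
        P = trial200.predictors()
        state = rf_impute_fit(P, seed=1, max_iter=1, n_estimators=20)
        X = standardize_and_encode(state, P)
        eth = [c for c in X.columns if c.startswith("ethnicity=")]
        assert len(eth) == 4
        assert np.allclose(X[eth].sum(axis=1), 1.0)

    def test_unseen_level_encodes_all_zero_with_warning(self):
        df = _toy_frame(50, seed=7)
        state = rf_impute_fit(df, seed=0)
        probe = df.iloc[[0]].copy()
        probe["color"] = "violet"
        with pytest.warns(UserWarning, match="unseen"):
            enc = standardize_and_encode(state, probe)
        assert enc[[c for c in enc.columns if c.startswith("color=")]].sum().sum() == 0.0

    def test_schema_mismatch_raises(self):
        df = _toy_frame(30, seed=8)
        state = rf_impute_fit(df, seed=0)
        with pytest.raises(ValueError):
            standardize_and_encode(state, df.drop(columns=["x2"]))
        with pytest.raises(ValueError):
            standardize_and_encode(state, df.assign(extra=1.0))

    def test_transform_never_mutates_fitted_state(self):
        df = _toy_frame(60, seed=9, missing={"x2": [0, 3]})
        state = rf_impute_fit(df, seed=0)
        fingerprint = joblib.hash(
            (state.means, state.sds, state.fill_values, state.level_registry, state.n_passes)
        )
        standardize_and_encode(state, _toy_frame(25, seed=10, missing={"x1": [1]}))
        after = joblib.hash(
            (state.means, state.sds, state.fill_values, state.level_registry, state.n_passes)
        )
        assert fingerprint == after


class TestSmote:
    def test_synthetic_points_lie_on_minority_segment(self):
        X = pd.DataFrame(
            {
                "u": [0.0, 1.0, 5.0, 6.0, 7.0, 8.0, 9.0],
                "v": [0.0, 1.0, 5.0, 6.0, 7.0, 8.0, 9.0],
            }
        )
        y = np.array([1, 1, 0, 0, 0, 0, 0])
        with pytest.warns(UserWarning, match="reducing k"):
            reb = smote_rebalance(X, y, k_neighbors=5, seed=0)
        synth = reb.features[reb.provenance == "synthetic"]
        # with minority (0,0),(1,1) and k=1, synthetic points are (lam, lam)
        assert np.allclose(synth["u"], synth["v"])
        assert ((synth["u"] >= 0) & (synth["u"] <= 1)).all()

    def test_midpoint_then_parity_counts(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(100, 3)))
        y = np.r_[np.ones(20, dtype=int), np.zeros(80, dtype=int)]
        reb = smote_rebalance(X, y, seed=1)
        counts = np.bincount(reb.labels)
        assert counts[0] == 50 and counts[1] == 50

    def test_balanced_input_is_noop(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(40, 2)))
        y = np.r_[np.ones(20, dtype=int), np.zeros(20, dtype=int)]
        reb = smote_rebalance(X, y, seed=0)
        pd.testing.assert_frame_equal(reb.features, X)
        assert (reb.provenance == "original").all()

    def test_provenance_flags_mark_synthetic_rows(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(60, 4)))
        y = (np.arange(60) < 12).astype(int)
        reb = smote_rebalance(X, y, seed=3)
        n_synth = (reb.provenance == "synthetic").sum()
        assert n_synth == np.bincount(reb.labels)[1] - 12
        assert (reb.labels[reb.provenance == "synthetic"] == 1).all()

    def test_singleton_minority_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            smote_rebalance(X, np.array([1, 0, 0, 0]), seed=0)
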