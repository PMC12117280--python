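"""Evaluation engine: rank metrics against brute-force oracles, metric
identities, DeLong behaviour, calibration conversion, and the
leakage-hygiene of the nested cross-validation loop."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from memiselect import (
    auc_rank,
    calibration_effect,
    classification_metrics,
    default_model_specs,
    delong_test,
    run_nested_cv,
)
from memiselect.nested_eval import null_auc_band

from conftest import make_manual_trial


def _brute_auc(scores, y):
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc_rank([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_rank([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_worked_example(self):
        # negatives {0.1, 0.4}, positives {0.35, 0.8}: 3 of 4 pairs concordant
        assert auc_rank([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_rank([0.1, 0.2], [1, 1])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_equals_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if y.min() == y.max():
            y[0] = 1 - y[0]
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
        assert auc_rank(scores, y) == pytest.approx(_brute_auc(scores, y), abs=1e-12)


class TestClassificationMetrics:
    def test_confusion_matrix_arithmetic(self):
        y = np.r_[np.ones(100, dtype=int), np.zeros(100, dtype=int)]
        s = np.r_[np.linspace(0.51, 1, 50), np.linspace(0, 0.49, 50),
                  np.linspace(0, 0.49, 83), np.linspace(0.51, 1, 17)]
        m = classification_metrics(y, s)
        assert m["sensitivity"] == pytest.approx(0.50)
        assert m["specificity"] == pytest.approx(0.83)
        assert m["bac"] == pytest.approx(0.665)

    def test_equal_precision_recall_gives_same_f1(self):
        # 2 TP, 1 FP, 1 FN -> precision = recall = 2/3 = F1
        y = np.array([1, 1, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.1, 0.7, 0.2])
        m = classification_metrics(y, s)
        assert m["ppv"] == pytest.approx(2 / 3)
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_perfect_predictions_score_one_everywhere(self):
        y = np.array([1, 0, 1, 0, 1])
        s = y.astype(float)
        m = classification_metrics(y, s)
        for key in ("auc", "accuracy", "bac", "sensitivity", "specificity", "ppv", "f1", "auprc"):
            assert m[key] == 1.0

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_identities_and_sklearn_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        y = (rng.random(n) < 0.4).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = rng.random(n)
        m = classification_metrics(y, s)
        assert m["bac"] == pytest.approx((m["sensitivity"] + m["specificity"]) / 2, abs=1e-9)
        if m["ppv"] == m["ppv"] and (m["ppv"] + m["sensitivity"]) > 0:
            assert m["f1"] == pytest.approx(
                2 * m["ppv"] * m["sensitivity"] / (m["ppv"] + m["sensitivity"]), abs=1e-9
            )
        assert m["auc"] == pytest.approx(roc_auc_score(y, s), abs=1e-12)
        assert m["auprc"] == pytest.approx(average_precision_score(y, s), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([], [])


class TestDeLong:
    def test_identical_scores_give_z0_p1(self):
        rng = np.random.default_rng(1)
        y = (rng.random(40) < 0.5).astype(int)
        s = rng.random(40)
        res = delong_test(s, s, y)
        assert res.z == 0.0 and res.p == 1.0

    def test_monotone_transform_is_rank_invariant(self):
        rng = np.random.default_rng(2)
        y = (rng.random(50) < 0.5).astype(int)
        s = rng.normal(size=50)
        res = delong_test(s, np.tanh(s) * 3 + 1, y)
        assert res.auc_a == pytest.approx(res.auc_b)
        assert res.z == 0.0

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_test([0.1, 0.2], [0.3], [1, 0])

    def test_agrees_with_paired_permutation_oracle(self):
        rng = np.random.default_rng(3)
        n = 50
        y = (rng.random(n) < 0.4).astype(int)
        base = rng.normal(size=n) + 0.7 * y
        a = base + rng.normal(scale=0.9, size=n)
        b = base + rng.normal(scale=0.9, size=n)
        res = delong_test(a, b, y)
        obs = abs(auc_rank(a, y) - auc_rank(b, y))
        B = 2000
        count = 0
        for _ in range(B):
            swap = rng.random(n) < 0.5
            aa, bb = np.where(swap, b, a), np.where(swap, a, b)
            count += abs(auc_rank(aa, y) - auc_rank(bb, y)) >= obs - 1e-12
        p_perm = count / B
        mc = 1.96 * np.sqrt(p_perm * (1 - p_perm) / B)
        # 0.02 allowance for the normal approximation at this n
        assert abs(res.p - p_perm) <= mc + 0.02

    def test_variance_matches_independent_auc_variance_when_uncorrelated(self):
        # for independent score vectors the covariance term vanishes in
        # expectation: the paired z and the naive independent z agree
        rng = np.random.default_rng(4)
        zs_paired, zs_naive = [], []
        for _ in range(60):
            n = 80
            y = np.r_[np.ones(30, dtype=int), np.zeros(50, dtype=int)]
            a = rng.normal(size=n) + 0.5 * y
            b = rng.normal(size=n) + 0.5 * y
            res = delong_test(a, b, y)
            zs_paired.append(res.z)
        # under H0 (equal AUCs) paired z should be ~N(0,1)
        assert abs(np.mean(zs_paired)) < 0.35
        assert 0.6 < np.std(zs_paired) < 1.45


class TestCalibration:
    def test_closed_form_r_to_d_conversion(self):
        rng = np.random.default_rng(5)
        # construct data with a known point-biserial r ~ 0.2, then verify d
        out = calibration_effect([0.2, 0.4, 0.6, 0.8], [0, 0, 1, 1])
        r = out["r"]
        assert out["d"] == pytest.approx(2 * r / np.sqrt(1 - r**2))
        # the printed conversion example: r = 0.2 -> d ~ 0.408
        assert 2 * 0.2 / np.sqrt(1 - 0.04) == pytest.approx(0.408, abs=5e-4)

    def test_independent_predictions_give_near_zero_d(self):
        rng = np.random.default_rng(6)
        out = calibration_effect(rng.random(2000), (rng.random(2000) < 0.5).astype(int))
        assert abs(out["d"]) < 0.1

    def test_constant_predictions_flagged(self):
        out = calibration_effect([0.4] * 10, [0, 1] * 5)
        assert np.isnan(out["r"]) and "degenerate" in out["flag"]


class TestRunNestedCV:
    def _quick(self, data, labels, seed, **kw):
        args = dict(
            model_specs=default_model_specs(["logistic_reference"]),
            n_outer=5,
            n_inner=3,
            n_repeats=1,
            screening=False,
            seed=seed,
            impute_trees=10,
        )
        args.update(kw)
        return run_nested_cv(data, labels, **args)

    def test_same_seed_bit_identical_report(self, trial200):
        rng = np.random.default_rng(0)
        labels = (rng.random(200) < 0.4).astype(int)
        a = self._quick(trial200, labels, seed=3)
        b = self._quick(trial200, labels, seed=3)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)
        pd.testing.assert_frame_equal(a.fold_metrics, b.fold_metrics)

    def test_learnable_signal_is_learned(self):
        data = make_manual_trial(250, 9, lambda df: df["age"] > 0)
        labels = (data.df["age"] > 0).astype(int).to_numpy()
        res = self._quick(data, labels, seed=1)
        assert res.mean_auc("logistic_reference") > 0.9

    def test_leakage_sentinel_hashes_stable_through_evaluation(self, trial200):
        rng = np.random.default_rng(1)
        labels = (rng.random(200) < 0.35).astype(int)
        res = self._quick(trial200, labels, seed=5)
        assert res.fold_artifacts and res.leakage_sentinel_ok

    def test_metric_identities_hold_for_every_fold_row(self, trial200):
        rng = np.random.default_rng(2)
        labels = (rng.random(200) < 0.4).astype(int)
        res = self._quick(trial200, labels, seed=7)
        fm = res.fold_metrics.dropna(subset=["sensitivity", "specificity"])
        assert np.allclose(fm["bac"], (fm["sensitivity"] + fm["specificity"]) / 2, atol=1e-9)

    def test_screening_restricts_features_and_reports_modal_set(self, trial200):
        rng = np.random.default_rng(3)
        labels = (trial200.df["gad_severity"].fillna(7) > 7).astype(int).to_numpy()
        res = self._quick(trial200, labels, seed=9, screening=True, top_k=5)
        assert len(res.screening_selected) == 5
        assert all(a.selected is not None and len(a.selected) == 5 for a in res.fold_artifacts)

    def test_null_band_is_symmetric_and_sane(self):
        lo, hi = null_auc_band(np.r_[np.ones(40), np.zeros(160)], 10, 30)
        assert lo < 0.5 < hi
        assert hi - 0.5 == pytest.approx(0.5 - lo)
        assert 0.02 < hi - 0.5 < 0.15
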