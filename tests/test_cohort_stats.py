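import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from brainshape import (
    compare_groups,
    delong_compare,
    km_logrank,
    make_sweep_cohort,
    roc_auc,
    simulate_hazard_cohort,
    spearman,
    threshold_sweep,
)
from brainshape.cohort_stats import validate_cohort_table


def brute_force_auc(scores, labels):
    """Exhaustive concordant-pair fraction over all case-control pairs."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0

    def test_pure_ties(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]).auc == 0.5

    def test_interleaved_equals_brute_force_count(self):
        # 9 case-control pairs, 6 concordant
        res = roc_auc([1, 2, 3, 4, 5, 6], [0, 1, 0, 1, 0, 1])
        assert res.auc == pytest.approx(6 / 9, abs=1e-15)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2, 3], [1, 1, 1])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(10, 60))
    def test_rank_formulation_matches_exhaustive_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, dtype=int)
        labels[: n // 3 + 1] = 1
        rng.shuffle(labels)
        scores = np.round(rng.standard_normal(n), 1)  # coarse grid forces ties
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        # complement symmetry
        assert res.auc + roc_auc(-scores, labels).auc == pytest.approx(1.0, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        scores = rng.standard_normal(200) + labels
        assert roc_auc(scores, labels).auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_youden_cutoff_reproduces_own_sens_spec(self, rng):
        labels = np.r_[np.zeros(60, dtype=int), np.ones(40, dtype=int)]
        scores = rng.standard_normal(100) + labels
        res = roc_auc(scores, labels)
        sens = (scores[labels == 1] > res.youden_cutoff).mean()
        spec = (scores[labels == 0] <= res.youden_cutoff).mean()
        assert sens == res.youden_sensitivity
        assert spec == res.youden_specificity

    def test_ci_contains_auc_and_is_ordered(self, rng):
        labels = np.r_[np.zeros(50, dtype=int), np.ones(50, dtype=int)]
        scores = rng.standard_normal(100) + 0.8 * labels
        res = roc_auc(scores, labels)
        lo, hi = res.ci95
        assert 0 <= lo <= res.auc <= hi <= 1


class TestDelong:
    def test_identical_scores_give_p_one(self):
        labels = [0, 0, 1, 1]
        out = delong_compare([1, 2, 3, 4], [1, 2, 3, 4], labels)
        assert out["p_value"] == 1.0

    def test_symmetric_in_arguments(self, rng):
        labels = np.r_[np.zeros(30, dtype=int), np.ones(30, dtype=int)]
        a = rng.standard_normal(60) + labels
        b = rng.standard_normal(60) + 0.5 * labels
        ab = delong_compare(a, b, labels)
        ba = delong_compare(b, a, labels)
        assert ab["z"] == pytest.approx(-ba["z"], abs=1e-12)
        assert ab["p_value"] == pytest.approx(ba["p_value"], abs=1e-12)

    def test_maximal_difference_significant(self):
        labels = np.r_[np.zeros(10, dtype=int), np.ones(10, dtype=int)]
        a = np.arange(20.0)  # AUC 1
        out = delong_compare(a, -a, labels)
        assert out["auc_a"] == 1.0 and out["auc_b"] == 0.0
        assert out["p_value"] < 0.01

    def test_null_type_i_error(self):
        rng = np.random.default_rng(42)
        labels = np.r_[np.zeros(100, dtype=int), np.ones(100, dtype=int)]
        rejections = 0
        reps = 500
        for _ in range(reps):
            a = rng.standard_normal(200) + labels
            b = rng.standard_normal(200) + labels
            rejections += delong_compare(a, b, labels)["p_value"] < 0.05
        assert 0.03 <= rejections / reps <= 0.08


class TestKmLogrank:
    @staticmethod
    def _toy_table():
        # high stratum: events at 6, 12, 18; low stratum: censored at 48
        return pd.DataFrame(
            {
                "subject_id": list("abcdef"),
                "score": [2.0, 2.0, 2.0, 0.0, 0.0, 0.0],
                "event": [1, 1, 1, 0, 0, 0],
                "time_months": [6.0, 12.0, 18.0, 48.0, 48.0, 48.0],
            }
        )

    def test_hand_computed_logrank_tables(self):
        # observed-minus-expected over the three 2x2 risk tables:
        # t=6:  (3 high, 3 low at risk, 1 event)  O-E = 1 - 3/6,   V = (3/6)(3/6)(5/5)
        # t=12: (2 high, 3 low at risk, 1 event)  O-E = 1 - 2/5,   V = (2/5)(3/5)(4/4)
        # t=18: (1 high, 3 low at risk, 1 event)  O-E = 1 - 1/4,   V = (1/4)(3/4)(3/3)
        o_minus_e = (1 - 3 / 6) + (1 - 2 / 5) + (1 - 1 / 4)
        var = (3 / 6) * (3 / 6) + (2 / 5) * (3 / 5) + (1 / 4) * (3 / 4)
        expected_chi2 = o_minus_e**2 / var
        res = km_logrank(self._toy_table(), "score", 1.0)
        assert res.chi2 == pytest.approx(expected_chi2, rel=1e-12)
        assert res.p_value < 0.05
        assert res.hr > 100  # monotone likelihood: all events in the high stratum

    def test_exchangeable_strata_are_null(self):
        table = pd.DataFrame(
            {
                "score": [2.0, 0.0, 2.0, 0.0],
                "event": [1, 1, 0, 0],
                "time_months": [12.0, 12.0, 48.0, 48.0],
            }
        )
        res = km_logrank(table, "score", 1.0)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.hr == pytest.approx(1.0, abs=1e-9)

    def test_time_rescaling_invariance(self):
        df = simulate_hazard_cohort(n=200, true_hr=4.0, seed=9)
        res1 = km_logrank(df, "shape_feature", 1.54)
        df2 = df.assign(time_months=df.time_months * 2.5)
        res2 = km_logrank(df2, "shape_feature", 1.54)
        assert res2.hr == pytest.approx(res1.hr, rel=1e-9)
        assert res2.chi2 == pytest.approx(res1.chi2, rel=1e-12)

    def test_against_lifelines(self):
        from lifelines import CoxPHFitter
        from lifelines.statistics import logrank_test

        df = simulate_hazard_cohort(n=334, true_hr=5.0, seed=3)
        res = km_logrank(df, "shape_feature", 1.54)
        high = df.shape_feature > 1.54
        lr = logrank_test(
            df.time_months[high], df.time_months[~high], df.event[high], df.event[~high]
        )
        assert res.chi2 == pytest.approx(lr.test_statistic, rel=1e-9)
        fit = CoxPHFitter().fit(
            df.assign(high=high.astype(int))[["time_months", "event", "high"]],
            "time_months",
            "event",
        )
        # Breslow vs Efron ties: continuous times, so near-exact agreement
        assert res.hr == pytest.approx(float(np.exp(fit.params_.iloc[0])), rel=1e-3)

    def test_km_curves_start_at_one_and_decrease(self):
        df = simulate_hazard_cohort(n=150, true_hr=3.0, seed=1)
        res = km_logrank(df, "shape_feature", 1.54)
        for curve in res.curves.values():
            values = curve.iloc[:, 0].to_numpy()
            assert values[0] == 1.0
            assert (np.diff(values) <= 1e-12).all()

    def test_empty_stratum_rejected(self):
        df = simulate_hazard_cohort(n=100, seed=0)
        with pytest.raises(ValueError, match="stratum"):
            km_logrank(df, "shape_feature", df.shape_feature.max() + 1)

    def test_validate_rejects_missing_columns(self):
        with pytest.raises(ValueError, match="required column"):
            validate_cohort_table(pd.DataFrame({"event": [0, 1]}))


class TestSpearmanAndGroups:
    def test_identity_and_reversal(self):
        x = np.arange(10.0)
        assert spearman(x, x)["rho"] == pytest.approx(1.0)
        assert spearman(x, -x)["rho"] == pytest.approx(-1.0)

    def test_rank_example(self):
        out = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert out["rho"] == pytest.approx(0.8, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_identical_groups_t_null(self):
        table = pd.DataFrame({"group": ["a"] * 4 + ["b"] * 4, "v": [1.0, 2.0, 3.0, 4.0] * 2})
        out = compare_groups(table, "v")
        assert out["test"] == "welch_t"
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p_value"] == pytest.approx(1.0)

    def test_perfectly_aligned_contingency_chi2(self):
        # 2x2 table ((10,0),(0,10)): chi2 = N = 20 without continuity correction
        table = pd.DataFrame({"group": ["a"] * 10 + ["b"] * 10, "v": ["x"] * 10 + ["y"] * 10})
        out = compare_groups(table, "v")
        assert out["test"] == "pearson_chi2"
        assert out["statistic"] == pytest.approx(20.0, rel=1e-12)

    def test_table1_effect_size_detected(self):
        from brainshape import CohortSpec, simulate_cohort

        df = simulate_cohort(CohortSpec(seed=11))
        assert compare_groups(df, "bass")["p_value"] < 0.001


@pytest.fixture(scope="module")
def sweep_cohort():
    return make_sweep_cohort(n_per_group=15, seed=0)


class TestThresholdSweep:

    def test_five_row_table_with_peak_at_half_max(self, sweep_cohort):
        volumes, labels = sweep_cohort
        res = threshold_sweep(volumes, labels)
        assert len(res.table) == 5
        assert list(res.table.fraction) == [0.3, 0.4, 0.5, 0.6, 0.7]
        assert res.best_fraction == 0.5

    def test_shape_feature_downstream_requires_bai(self, sweep_cohort):
        volumes, labels = sweep_cohort
        with pytest.raises(ValueError, match="bai"):
            threshold_sweep(volumes, labels, downstream="shape_feature")
        bai = np.linspace(3.5, 4.5, len(volumes))
        res = threshold_sweep(volumes, labels, fractions=(0.5,), downstream="shape_feature", bai=bai)
        assert len(res.table) == 1

    def test_permuted_labels_are_null(self, sweep_cohort):
        # a single permutation is noisy at n=30; average a few draws
        volumes, labels = sweep_cohort
        rng = np.random.default_rng(1)
        aucs = np.mean(
            [threshold_sweep(volumes, rng.permutation(labels)).table.auc for _ in range(5)], axis=0
        )
        assert np.abs(aucs - 0.5).max() < 0.15
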