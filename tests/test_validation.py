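import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lnnb_flowscore.validation import (
    bootstrap_roc_band,
    dispersion_from_moments,
    low_motility_labels,
    pearson,
    roc_curve,
    specificity_at_sensitivity,
    summarize_scores,
    validate_paired_scores,
)


# ---------------------------------------------------------------- oracles
def auc_by_pairwise_comparison(labels, scores, lower_is_positive=True):
    """Brute-force O(n^2) Mann-Whitney AUC with ties counted 1/2."""
    labels = np.asarray(labels, bool)
    s = -np.asarray(scores, float) if lower_is_positive else np.asarray(scores, float)
    pos, neg = s[labels], s[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def spec_at_sens_by_enumeration(labels, scores, target):
    """Exhaustive sweep of thresholds (rule: score <= thr is positive)."""
    labels = np.asarray(labels, bool)
    scores = np.asarray(scores, float)
    best = (-1.0, np.inf)  # (specificity, threshold)
    for thr in np.concatenate([[-np.inf], np.unique(scores)]):
        pred = scores <= thr
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        if sens >= target - 1e-12 and (
            spec > best[0] or (spec == best[0] and thr < best[1])
        ):
            best = (spec, thr)
    return best


# ---------------------------------------------------------------- pearson
class TestPearson:
    def test_perfect_positive_linearity(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-8

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 4/3, sd_x = sd_y = sqrt(5/3): r = 4/5 by the covariance formula
        r, _ = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_errors(self):
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=20),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_affine_invariance(self, xs, a, b):
        xs = np.asarray(xs)
        ys = np.linspace(0, 1, len(xs)) + 0.1 * np.sin(np.arange(len(xs)))
        if np.std(xs) == 0:
            return
        r0, _ = pearson(xs, ys)
        r_pos, _ = pearson(a * xs + b, ys)
        r_neg, _ = pearson(-a * xs + b, ys)
        assert r_pos == pytest.approx(r0, abs=1e-9)
        assert r_neg == pytest.approx(-r0, abs=1e-9)


# ------------------------------------------------------------- labelling
class TestLowMotilityLabels:
    def test_below_mean_rule(self):
        assert low_motility_labels([1, 2, 3, 4]).tolist() == [True, True, False, False]

    def test_ties_at_mean_are_negative(self):
        assert not low_motility_labels([5, 5, 5, 5]).any()

    def test_two_values(self):
        assert low_motility_labels([0, 10]).tolist() == [True, False]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            low_motility_labels([1])


# ------------------------------------------------------------------- ROC
class TestRocCurve:
    def test_perfect_separation(self):
        labels = [True, True, False, False]
        scores = [0.1, 0.2, 0.8, 0.9]  # positives score lower
        roc = roc_curve(labels, scores)
        assert roc.auc == pytest.approx(1.0)

    def test_chance_level_on_independent_scores(self):
        rng = np.random.default_rng(0)
        labels = rng.random(2000) < 0.5
        scores = rng.random(2000)
        roc = roc_curve(labels, scores)
        assert roc.auc == pytest.approx(0.5, abs=0.05)

    def test_curve_spans_both_endpoints(self):
        roc = roc_curve([True, False, True, False], [1, 2, 3, 4])
        pts = set(zip(roc.sensitivity.round(9), roc.specificity.round(9)))
        assert (0.0, 1.0) in pts and (1.0, 0.0) in pts

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([True, True], [1, 2])

    def test_auc_equals_mann_whitney_on_random_instances(self):
        """AUC identity with the pairwise U statistic, ties included."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(4, 30)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            # integer scores force ties
            scores = rng.integers(0, 6, n).astype(float)
            roc = roc_curve(labels, scores)
            oracle = auc_by_pairwise_comparison(labels, scores)
            assert roc.auc == pytest.approx(oracle, abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        labels = rng.random(50) < 0.4
        labels[:2] = [True, False]
        scores = rng.random(50)
        r1 = roc_curve(labels, scores)
        r2 = roc_curve(labels, np.exp(3 * scores))
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)
        assert np.allclose(r1.sensitivity, r2.sensitivity)


class TestSpecificityAtSensitivity:
    def test_perfect_separation_target_70(self):
        roc = roc_curve([True, True, False, False], [1, 2, 3, 4])
        res = specificity_at_sensitivity(roc, 0.70)
        assert res.specificity == 1.0

    def test_hand_enumerated_thresholds(self):
        labels = [True, True, False, False]
        scores = [1.0, 2.0, 3.0, 4.0]
        res = specificity_at_sensitivity(roc_curve(labels, scores), 1.0)
        assert res.specificity == 1.0
        assert res.threshold == pytest.approx(2.0)
        assert res.sensitivity == 1.0

    def test_degenerate_identical_scores(self):
        labels = [True, False, True, False]
        roc = roc_curve(labels, [5.0, 5.0, 5.0, 5.0])
        res = specificity_at_sensitivity(roc, 0.7)
        assert res.specificity == 0.0
        assert res.sensitivity == 1.0

    def test_matches_enumeration_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(6, 40)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            scores = rng.integers(0, 8, n).astype(float)
            target = rng.choice([0.5, 0.7, 0.9, 1.0])
            res = specificity_at_sensitivity(roc_curve(labels, scores), target)
            spec_o, thr_o = spec_at_sens_by_enumeration(labels, scores, target)
            assert res.specificity == pytest.approx(spec_o, abs=1e-12)

    def test_bad_target_rejected(self):
        roc = roc_curve([True, False], [1, 2])
        with pytest.raises(ValueError):
            specificity_at_sensitivity(roc, 1.5)


class TestBootstrapRocBand:
    @staticmethod
    def _data(n=46, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.arange(n) < n // 2
        scores = rng.normal(loc=np.where(labels, 0.0, 1.0))
        return labels, scores

    def test_deterministic_given_seed(self):
        labels, scores = self._data()
        b1 = bootstrap_roc_band(labels, scores, n_boot=200, seed=5)
        b2 = bootstrap_roc_band(labels, scores, n_boot=200, seed=5)
        assert np.array_equal(b1.tpr_low, b2.tpr_low)
        assert np.array_equal(b1.tpr_high, b2.tpr_high)
        assert b1.auc_ci == b2.auc_ci

    def test_band_contains_point_estimate(self):
        labels, scores = self._data()
        band = bootstrap_roc_band(labels, scores, n_boot=200, seed=1)
        assert np.all(band.tpr_low <= band.tpr_point + 1e-12)
        assert np.all(band.tpr_high >= band.tpr_point - 1e-12)

    def test_band_narrows_with_sample_size(self):
        w = {}
        for n in (46, 460):
            labels, scores = self._data(n=n, seed=2)
            band = bootstrap_roc_band(labels, scores, n_boot=300, seed=3)
            w[n] = np.mean(band.tpr_high - band.tpr_low)
        assert w[460] < w[46]

    def test_small_n_boot_rejected(self):
        labels, scores = self._data()
        with pytest.raises(ValueError):
            bootstrap_roc_band(labels, scores, n_boot=50, seed=0)


# ---------------------------------------------------------------- summary
class TestSummarizeScores:
    @pytest.mark.parametrize(
        "mean, sd, expected",
        [(23.48, 7.54, 2.42), (17.5, 6.31, 2.28), (9.67, 2.86, 0.85), (9.13, 2.96, 0.96)],
    )
    def test_dispersion_from_printed_moments(self, mean, sd, expected):
        """SD^2/mean reproduces the reported dispersion values to 2 d.p."""
        assert round(dispersion_from_moments(mean, sd), 2) == expected

    def test_constant_sequence(self):
        row = summarize_scores([5.0, 5.0, 5.0])
        assert row["sd"] == 0.0
        assert row["dispersion"] == 0.0

    def test_moments_and_quartiles(self):
        row = summarize_scores([1, 2, 3, 4, 5])
        assert row["mean"] == 3.0
        assert row["sd"] == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1))
        assert row["q1"] == 2.0 and row["median"] == 3.0 and row["q3"] == 4.0
        assert row["min"] == 1.0 and row["max"] == 5.0

    def test_zero_mean_dispersion_missing(self):
        row = summarize_scores([-1.0, 1.0])
        assert np.isnan(row["dispersion"])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            summarize_scores([1.0])


# --------------------------------------------------------- orchestration
class TestValidatePairedScores:
    def test_full_run_on_synthetic_table(self):
        from lnnb_flowscore.synthetic import gen_paired_scores

        df = gen_paired_scores(n=46, rho=0.72, seed=11)
        res = validate_paired_scores(df, n_boot=200, seed=0)
        row = res["correlations"].iloc[0]
        assert 0.4 < row["pearson_r"] < 0.95
        assert 0.5 <= row["auc"] <= 1.0
        assert row["n_low_motility"] > 0
        assert len(res["summary"]) == 2

    def test_missing_column_named_in_error(self):
        import pandas as pd

        df = pd.DataFrame({"subject_id": ["a"], "task_id": [1], "conventional": [3]})
        with pytest.raises(ValueError, match="image_derived"):
            validate_paired_scores(df)
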