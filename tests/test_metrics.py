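import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from advdta.metrics import (BinaryLabeledScores, CorrelationPair,
                            PredictionSet, aupr, binarize_affinities,
                            concordance_index, metric_report, mse, rm2_index,
                            squared_correlations, step_function)


def brute_force_ci(p, y):
    """Independent O(n^2) oracle: direct pair enumeration of the definition."""
    num = z = 0.0
    for i in range(len(y)):
        for j in range(len(y)):
            if y[i] > y[j]:
                z += 1
                diff = p[i] - p[j]
                num += 1.0 if diff > 0 else (0.5 if diff == 0 else 0.0)
    return num / z


class TestStepFunction:
    @pytest.mark.parametrize("m,expected", [(0.3, 1.0), (0.0, 0.5), (-2.0, 0.0)])
    def test_printed_values(self, m, expected):
        assert step_function(m) == expected

    def test_vectorised(self):
        assert np.array_equal(step_function([-1, 0, 2]), [0.0, 0.5, 1.0])

    def test_complement_identity(self, rng):
        m = rng.standard_normal(100)
        assert np.allclose(step_function(m) + step_function(-m), 1.0)


class TestConcordanceIndex:
    def test_perfect_ranking(self):
        assert concordance_index(PredictionSet([0.1, 0.2, 0.3], [1, 2, 3])) == 1.0

    def test_reversed_ranking(self):
        assert concordance_index(PredictionSet([3, 2, 1], [1, 2, 3])) == 0.0

    def test_tied_predictions_score_half(self):
        ci = concordance_index(PredictionSet([1, 1, 2], [1, 2, 3]))
        assert ci == pytest.approx(2.5 / 3)

    def test_all_equal_truths_undefined(self):
        with pytest.raises(ValueError, match="Z=0"):
            concordance_index(PredictionSet([1, 2, 3], [5, 5, 5]))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 60))
            y = rng.choice([1.0, 2.0, 3.0, 4.0], n) if rng.random() < 0.5 \
                else rng.standard_normal(n)
            p = np.round(rng.standard_normal(n), 1)  # induces prediction ties
            if np.all(y == y[0]):
                continue
            ps = PredictionSet(p, y)
            assert concordance_index(ps) == pytest.approx(brute_force_ci(p, y), abs=1e-12)

    def test_complement_on_tie_free_predictions(self, rng):
        y = rng.standard_normal(30)
        p = rng.permutation(30).astype(float)  # distinct predictions
        ci = concordance_index(PredictionSet(p, y))
        ci_neg = concordance_index(PredictionSet(-p, y))
        assert ci + ci_neg == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.standard_normal(40)
        p = rng.standard_normal(40)
        base = concordance_index(PredictionSet(p, y))
        for f in (lambda x: 3 * x + 2, np.tanh, lambda x: np.exp(x / 2)):
            assert concordance_index(PredictionSet(f(p), y)) == pytest.approx(base)


class TestSquaredCorrelations:
    def test_identity_predictions(self, rng):
        y = rng.standard_normal(20)
        cp = squared_correlations(PredictionSet(y, y))
        assert cp.r2 == pytest.approx(1.0)
        assert cp.r02 == pytest.approx(1.0)

    def test_exact_scaling_through_origin(self, rng):
        y = rng.uniform(1, 5, 20)
        cp = squared_correlations(PredictionSet(2 * y, y))
        # y = 0.5 p holds exactly through the origin
        assert cp.r2 == pytest.approx(1.0)
        assert cp.r02 == pytest.approx(1.0)

    def test_r02_matches_least_squares_oracle(self, rng):
        p = rng.uniform(1, 10, 50)
        y = 0.7 * p + rng.standard_normal(50)
        cp = squared_correlations(PredictionSet(p, y))
        k = np.linalg.lstsq(p[:, None], y, rcond=None)[0][0]
        r02 = 1 - np.sum((y - k * p) ** 2) / np.sum((y - y.mean()) ** 2)
        assert cp.r02 == pytest.approx(r02, abs=1e-10)
        assert cp.r2 == pytest.approx(np.corrcoef(p, y)[0, 1] ** 2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            squared_correlations(PredictionSet([1, 1, 1], [1, 2, 3]))


class TestRm2:
    def test_equal_correlations_collapse_to_r2(self):
        assert rm2_index(CorrelationPair(0.81, 0.81)) == pytest.approx(0.81)

    def test_perfect_model(self):
        assert rm2_index(CorrelationPair(1.0, 1.0)) == 1.0

    def test_hand_computed_value(self):
        assert rm2_index(CorrelationPair(0.75, 0.50)) == pytest.approx(0.375)

    def test_negative_radicand_clamped(self):
        assert rm2_index(CorrelationPair(0.5, 0.6)) == pytest.approx(0.5)

    def test_never_exceeds_r2(self, rng):
        for _ in range(1000):
            r2 = rng.uniform(0, 1)
            r02 = rng.uniform(-0.5, 1)
            rm2 = rm2_index(CorrelationPair(r2, r02))
            assert rm2 <= r2 + 1e-12
            if abs(r2 - r02) > 1e-9 and r02 < r2:
                assert rm2 < r2


class TestBinarize:
    def test_davis_pkd_threshold(self):
        assert binarize_affinities([5.0, 7.0, 9.1], 7.0).tolist() == [0, 1, 1]

    def test_kiba_threshold(self):
        assert binarize_affinities([12.0, 12.1, 12.2], 12.1).tolist() == [0, 1, 1]

    def test_empty_vector(self):
        assert binarize_affinities([], 7.0).size == 0


class TestAupr:
    def test_perfect_separation(self):
        bs = BinaryLabeledScores(np.array([0.9, 0.8, 0.2, 0.1]),
                                 np.array([1, 1, 0, 0]), 0.5)
        assert aupr(bs) == 1.0

    def test_rank_by_rank_example(self):
        bs = BinaryLabeledScores(np.array([0.9, 0.8, 0.1]),
                                 np.array([1, 0, 1]), 0.5)
        assert aupr(bs) == pytest.approx((1.0 + 2.0 / 3.0) / 2.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            aupr(BinaryLabeledScores(np.array([0.1, 0.2]), np.array([1, 1]), 0.5))

    def test_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = rng.standard_normal(n)
            labels = (rng.random(n) < 0.4).astype(int)
            if labels.sum() in (0, n):
                continue
            ours = aupr(BinaryLabeledScores(scores, labels, 0.0))
            assert ours == pytest.approx(average_precision_score(labels, scores),
                                         abs=1e-10)

    def test_close_to_trapezoidal_pr_area(self, rng):
        from sklearn.metrics import precision_recall_curve
        scores = rng.standard_normal(2000)
        labels = (rng.random(2000) < 0.5).astype(int)
        ours = aupr(BinaryLabeledScores(scores, labels, 0.0))
        prec, rec, _ = precision_recall_curve(labels, scores)
        trap = -np.trapezoid(prec, rec)
        assert ours == pytest.approx(trap, abs=0.02)


class TestMetricReport:
    def test_full_battery(self, rng):
        y = rng.uniform(4, 10, 100)
        p = y + rng.normal(0, 0.5, 100)
        report = metric_report(PredictionSet(p, y), threshold=7.0)
        assert set(report) >= {"ci", "mse", "rm2", "aupr", "n", "threshold"}
        assert report["n"] == 100
        assert 0 <= report["ci"] <= 1
        assert report["mse"] == pytest.approx(mse(PredictionSet(p, y)))

    def test_single_class_marks_aupr_unavailable(self, rng):
        y = rng.uniform(8, 10, 50)  # all above threshold
        p = y + rng.normal(0, 0.1, 50)
        report = metric_report(PredictionSet(p, y), threshold=7.0)
        assert report["aupr"] is None
        assert "positive and a negative" in report["aupr_unavailable_reason"]


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=2, max_size=30),
       st.integers(0, 2 ** 31 - 1))
def test_ci_bounds_property(truths, seed):
    """CI always lands in [0, 1] whenever it is defined."""
    y = np.asarray(truths)
    if np.all(y == y[0]):
        return
    p = np.random.default_rng(seed).standard_normal(len(y))
    ci = concordance_index(PredictionSet(p, y))
    assert 0.0 <= ci <= 1.0
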