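import numpy as np
import pytest

import plastiscreen as ps
from plastiscreen.metrics import ConfusionCounts, f1_from_pr


class TestPrecisionRecallF1:
    def test_worked_confusion(self):
        p, r, f1 = ps.precision_recall_f1(ConfusionCounts(TP=8, FP=2, FN=4, TN=10))
        assert p == pytest.approx(0.8)
        assert r == pytest.approx(8 / 12)
        assert f1 == pytest.approx(2 * 0.8 * (8 / 12) / (0.8 + 8 / 12))

    def test_degenerate_zero_counts(self):
        assert ps.precision_recall_f1(ConfusionCounts()) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "p,r,expected",
        [(0.84, 1.00, 0.91), (1.00, 0.76, 0.86), (0.63, 0.88, 0.73), (0.98, 0.96, 0.97)],
    )
    def test_f1_from_pr_two_decimal_rounding(self, p, r, expected):
        assert round(f1_from_pr(p, r), 2) == expected

    def test_harmonic_mean_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = ConfusionCounts(*rng.integers(0, 30, size=4))
            p, r, f1 = ps.precision_recall_f1(c)
            if p + r > 0:
                assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12


class TestMCC:
    def test_perfect_and_inverted(self):
        assert ps.mcc(ConfusionCounts(TP=5, TN=10)) == pytest.approx(1.0)
        assert ps.mcc(ConfusionCounts(FP=10, FN=5)) == pytest.approx(-1.0)

    def test_worked_value(self):
        c = ConfusionCounts(TP=5, FP=0, FN=2, TN=10)
        assert ps.mcc(c) == pytest.approx(50 / np.sqrt(4200), rel=1e-9)

    def test_zero_marginal_convention(self):
        assert ps.mcc(ConfusionCounts(TP=0, FP=0, FN=3, TN=5)) == 0.0

    def test_symmetry_under_class_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            tp, fp, fn, tn = rng.integers(0, 20, size=4)
            a = ps.mcc(ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn))
            b = ps.mcc(ConfusionCounts(TP=tn, FP=fn, FN=fp, TN=tp))
            assert a == pytest.approx(b, abs=1e-12)


def accuracy(y_true, y_pred):
    return float((np.asarray(y_true) == np.asarray(y_pred)).mean())


class TestBootstrap:
    def test_perfect_predictions_zero_variance(self):
        y = np.array([1, 0, 1, 1, 0, 1])
        mean, lo, hi = ps.bootstrap_ci(y, y, accuracy, n=200, seed=1)
        assert (mean, lo, hi) == (1.0, 1.0, 1.0)

    def test_interval_ordering(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=100)
        p = np.where(rng.random(100) < 0.8, y, 1 - y)
        mean, lo, hi = ps.bootstrap_ci(y, p, accuracy, n=500, seed=2)
        assert lo <= mean <= hi

    def test_reordering_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=60)
        p = rng.integers(0, 2, size=60)
        r1 = ps.bootstrap_ci(y, p, accuracy, n=300, seed=9)
        perm = rng.permutation(60)
        r2 = ps.bootstrap_ci(y[perm], p[perm], accuracy, n=300, seed=9)
        assert r1 == r2

    def test_coverage_of_known_accuracy(self):
        """Bernoulli(0.8) correctness: the 95% CI should cover the true value
        in roughly 95% of simulations."""
        true_acc = 0.8
        rng = np.random.default_rng(29)
        covered = 0
        reps = 200
        for _ in range(reps):
            y = rng.integers(0, 2, size=500)
            pred = np.where(rng.random(500) < true_acc, y, 1 - y)
            _, lo, hi = ps.bootstrap_ci(y, pred, accuracy, n=200, seed=int(rng.integers(2**31)))
            if lo <= true_acc <= hi:
                covered += 1
        assert 0.90 <= covered / reps <= 0.99

    def test_all_undefined_resamples_error(self):
        def undefined(y_true, y_pred):
            return float("nan")

        with pytest.raises(ValueError, match="undefined"):
            ps.bootstrap_ci([1, 0, 1], [1, 0, 1], undefined, n=50, seed=0)


class TestPairedTTest:
    def test_textbook_worked_example(self):
        b = np.array([10.0, 12.0, 9.0, 11.0, 10.0])
        d = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        t, p = ps.paired_ttest(b + d, b)
        assert t == pytest.approx(1.8 / (np.std(d, ddof=1) / np.sqrt(5)), rel=1e-6)
        assert t == pytest.approx(4.811, abs=2e-3)
        assert 0 < p < 0.01

    def test_sign_follows_mean_difference(self):
        rng = np.random.default_rng(4)
        b = rng.normal(size=20)
        jitter = rng.normal(0, 0.01, size=20)
        t_pos, _ = ps.paired_ttest(b + 1 + jitter, b)
        t_neg, _ = ps.paired_ttest(b - 1 + jitter, b)
        assert t_pos > 0 > t_neg

    def test_zero_difference_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            ps.paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert ps.pearson_r(x, 2 * x) == pytest.approx(1.0)
        assert ps.pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert ps.pearson_r(x, y) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            ps.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBenchmarkConfusion:
    TRUTH = {"PET": {"p1", "p2"}, "PHB": {"h1"}, "negative": {"n1", "n2"}}

    def test_ko_scheme_mapping(self):
        preds = {
            "p1": {"K21104"},       # correct PET KO -> TP
            "p2": {"K00001"},       # wrong KO -> FN
            "h1": {"K05973"},       # correct PHB KO -> TP
            "n1": {"K05973"},       # plastizyme KO on a negative -> FP
            "n2": set(),            # -> TN
        }
        c = ps.benchmark_confusion(preds, self.TRUTH, scheme="ko")
        assert (c["PET"].TP, c["PET"].FN) == (1, 1)
        assert (c["PET"].FP, c["PET"].TN) == (1, 1)
        assert (c["PHB"].TP, c["PHB"].FN) == (1, 0)

    def test_score_scheme_strict_threshold(self):
        preds = {
            "p1": {"PET": 0.4},   # below 0.5 -> FN
            "p2": {"PET": 0.51},  # -> TP
            "h1": {"PHB": 0.5},   # not strictly greater -> FN
            "n1": {"PET": 0.9, "PHB": 0.1},
            "n2": {},
        }
        c = ps.benchmark_confusion(preds, self.TRUTH, scheme="score")
        assert (c["PET"].TP, c["PET"].FN) == (1, 1)
        assert c["PET"].FP == 1 and c["PET"].TN == 1
        assert c["PHB"].FN == 1

    def test_overlapping_truth_sets_error(self):
        bad = {"PET": {"a"}, "PHB": {"a"}, "negative": set()}
        with pytest.raises(ValueError, match="two truth sets"):
            ps.benchmark_confusion({}, bad)


class TestHitsPerMillion:
    def test_worked_values(self):
        assert ps.hits_per_million(1, 1_000_000) == 1.0
        assert ps.hits_per_million(0, 10) == 0.0
        assert ps.hits_per_million(2, 4_000_000) == 0.5

    def test_zero_proteins_errors(self):
        with pytest.raises(ValueError):
            ps.hits_per_million(1, 0)
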