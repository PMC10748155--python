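import numpy as np
import pytest

from cardiostack.stats import (
    binary_metrics,
    bootstrap_metrics,
    compare_models,
    roc_auc,
    select_models,
)


def brute_force_auc(scores, labels):
    """Independent pairwise oracle: P(s+ > s-) + 0.5 P(s+ == s-)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(5, 25))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            scores = np.round(rng.uniform(size=n), 2)  # coarse grid forces ties
            assert roc_auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.9], [1, 1])


class TestBinaryMetrics:
    def test_perfect_prediction(self):
        m = binary_metrics([0.1, 0.9, 0.2, 0.8], [0, 1, 0, 1])
        assert m == {"f1": 1.0, "sensitivity": 1.0, "specificity": 1.0}

    def test_all_negative_predictions(self):
        m = binary_metrics([0.1, 0.2, 0.3, 0.4], [0, 1, 0, 1])
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 1.0
        assert m["f1"] == 0.0


class TestBootstrap:
    def test_perfect_classifier_mean_one_sd_zero(self):
        scores = np.r_[np.full(20, 0.9), np.full(20, 0.1)]
        labels = np.r_[np.ones(20, dtype=int), np.zeros(20, dtype=int)]
        rep = bootstrap_metrics(scores, labels, B=50, seed=0)
        assert rep.means["auc"] == 1.0
        assert rep.sds["auc"] == 0.0

    def test_single_resample_sd_zero(self, rng):
        scores = rng.uniform(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        rep = bootstrap_metrics(scores, labels, B=1, seed=1)
        assert all(v == 0.0 for v in rep.sds.values())

    def test_uninformative_scores_centered_at_half(self):
        rng = np.random.default_rng(7)
        scores = rng.uniform(size=200)
        labels = rng.integers(0, 2, 200)
        rep = bootstrap_metrics(scores, labels, B=2000, seed=7)
        assert rep.means["auc"] == pytest.approx(0.5, abs=0.05)

    def test_invalid_B_rejected(self):
        with pytest.raises(ValueError, match="B"):
            bootstrap_metrics([0.1, 0.9], [0, 1], B=0)

    def test_sd_shrinks_with_sample_size(self):
        # SD of bootstrapped AUC decreases monotonically in n, roughly 1/sqrt(n)
        rng = np.random.default_rng(21)
        sds = []
        for n in (50, 100, 200, 400):
            labels = np.r_[np.ones(n // 2, dtype=int), np.zeros(n // 2, dtype=int)]
            scores = np.where(labels == 1, rng.normal(1.0, 1.0, n), rng.normal(0.0, 1.0, n))
            sds.append(bootstrap_metrics(scores, labels, B=300, seed=n).sds["auc"])
        assert all(b < a for a, b in zip(sds, sds[1:]))
        rate = sds[0] / sds[-1]  # expect ~ sqrt(400/50) ~ 2.83, within factor 2
        assert np.sqrt(8) / 2 < rate < np.sqrt(8) * 2


class TestCompareModels:
    def _reports(self, score_sets, labels, B=100):
        return [
            bootstrap_metrics(s, labels, B=B, seed=i, model=f"m{i}")
            for i, s in enumerate(score_sets)
        ]

    def test_identical_models_not_different(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        scores = rng.uniform(size=40)
        reports = [
            bootstrap_metrics(scores, labels, B=100, seed=0, model="a"),
            bootstrap_metrics(scores, labels, B=100, seed=0, model="b"),
        ]
        result = compare_models(reports)
        assert result.significant_pairs == []

    def test_clearly_different_models_detected(self):
        rng = np.random.default_rng(3)
        n = 200
        labels = np.r_[np.ones(n // 2, dtype=int), np.zeros(n // 2, dtype=int)]
        strong = np.where(labels == 1, rng.normal(2.3, 1.0, n), rng.normal(0, 1, n))
        weak = np.where(labels == 1, rng.normal(0.18, 1.0, n), rng.normal(0, 1, n))
        result = compare_models(self._reports([strong, weak], labels, B=500))
        assert ("m0", "m1") in result.significant_pairs
        assert result.ranking[0] == "m0"

    def test_three_models_three_pairs(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        reports = self._reports([rng.uniform(size=30) for _ in range(3)], labels)
        result = compare_models(reports)
        assert result.pairwise_pvalues.shape == (3, 3)
        k = 3
        assert k * (k - 1) // 2 == 3
        assert np.allclose(result.pairwise_pvalues, result.pairwise_pvalues.T)

    def test_mismatched_B_rejected(self, rng):
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        a = bootstrap_metrics(rng.uniform(size=20), labels, B=50, seed=0)
        b = bootstrap_metrics(rng.uniform(size=20), labels, B=60, seed=0)
        with pytest.raises(ValueError, match="resamples"):
            compare_models([a, b])


class TestSelectModels:
    METHODS = [f"method{i}" for i in range(14)]
    FOLDS = [0, 1, 2, 3]

    def test_each_method_keeps_best_fold(self):
        rng = np.random.default_rng(5)
        grid = {(m, f): float(rng.uniform()) for m in self.METHODS for f in self.FOLDS}
        top = select_models(grid, self.METHODS, self.FOLDS, k=14)
        assert len(top) == 14  # one survivor per method
        for entry in top:
            m = entry["method"]
            assert entry["test_auc"] == max(grid[(m, f)] for f in self.FOLDS)

    def test_known_maximum_selected(self):
        grid = {(m, f): 0.5 for m in self.METHODS for f in self.FOLDS}
        grid[("method7", 2)] = 0.99
        top = select_models(grid, self.METHODS, self.FOLDS)
        assert top[0] == {"method": "method7", "fold": 2, "test_auc": 0.99}

    def test_all_equal_breaks_ties_by_method_order(self):
        grid = {(m, f): 0.5 for m in self.METHODS for f in self.FOLDS}
        top = select_models(grid, self.METHODS, self.FOLDS)
        assert [e["method"] for e in top] == ["method0", "method1", "method2"]

    def test_missing_cell_rejected(self):
        grid = {(m, f): 0.5 for m in self.METHODS for f in self.FOLDS}
        del grid[("method3", 1)]
        with pytest.raises(ValueError, match="method3"):
            select_models(grid, self.METHODS, self.FOLDS)
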