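"""Bag aggregation against brute-force oracles, metric identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemil.mil import (Bag, BagPrediction, UndefinedMetricError, aggregate,
                       auc_rank, classify_bags, compute_metrics, f1_from_pr,
                       k_used_for, predict_bags)


def oracle_topk(probs, k):
    """Independent sort-and-slice pooling oracle."""
    top = sorted(probs, reverse=True)[: min(k, len(probs))]
    return sum(top) / len(top)


def oracle_auc(labels, scores):
    """All-pairs counting oracle, ties half-credited."""
    pos = [s for lab, s in zip(labels, scores) if lab == "high"]
    neg = [s for lab, s in zip(labels, scores) if lab == "low"]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAggregate:
    def test_worked_examples(self):
        assert aggregate([0.2, 0.4, 0.6], "mean") == pytest.approx(0.4)
        assert aggregate([0.9, 0.1, 0.5], "topk", k=2) == pytest.approx(0.7)
        assert aggregate([0.4, 0.8], "topk", k=10) == pytest.approx(0.6)
        assert k_used_for("topk", 2, k=10) == 2
        assert aggregate([0.3, 0.9, 0.2], "max") == pytest.approx(0.9)

    def test_matches_sort_and_slice_oracle_on_random_bags(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            probs = rng.uniform(0, 1, size=rng.integers(1, 201))
            for strat, k in [("mean", None), ("top10", None), ("top100", None),
                             ("max", None), ("topk", 7)]:
                got = aggregate(probs, strat, k)
                want = {"mean": np.mean(probs), "max": np.max(probs),
                        "top10": oracle_topk(probs, 10),
                        "top100": oracle_topk(probs, 100),
                        "topk": oracle_topk(probs, 7)}[strat]
                assert got == pytest.approx(want, abs=1e-12)

    def test_empty_bag_rejected(self):
        with pytest.raises(ValueError):
            aggregate([], "mean")

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_pooling_identities(self, probs):
        n = len(probs)
        assert aggregate(probs, "topk", k=1) == pytest.approx(aggregate(probs, "max"))
        assert aggregate(probs, "topk", k=n) == pytest.approx(aggregate(probs, "mean"),
                                                              abs=1e-12)
        assert aggregate(probs, "topk", k=n + 5) == pytest.approx(
            aggregate(probs, "mean"), abs=1e-12)
        # max >= top-k >= mean, non-increasing in k
        vals = [aggregate(probs, "topk", k=k) for k in range(1, n + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[0] >= vals[-1] - 1e-12

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30), st.randoms())
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_permutation_invariance(self, probs, rnd):
        shuffled = list(probs)
        rnd.shuffle(shuffled)
        for strat in ("mean", "top10", "max"):
            assert aggregate(shuffled, strat) == pytest.approx(
                aggregate(probs, strat), abs=1e-12)


class TestClassifyBags:
    def bp(self, prob):
        return BagPrediction("p", "mean", 1, prob)

    def test_threshold_boundary_inclusive(self):
        assert classify_bags([self.bp(0.5)])[0].predicted_label == "high"
        assert classify_bags([self.bp(0.4999)])[0].predicted_label == "low"

    def test_degenerate_threshold(self):
        out = classify_bags([self.bp(1.0), self.bp(0.0)], threshold=1.1)
        assert all(p.predicted_label == "low" for p in out)

    def test_bag_requires_instances(self):
        with pytest.raises(ValueError):
            Bag("p", [], "high")
        with pytest.raises(ValueError):
            Bag("p", ["a", "a"], "high")


class TestF1FromPR:
    @pytest.mark.parametrize("p,r,expect", [
        (5 / 13, 1.000, 0.5556),   # top-10 pooling row; 0.3846 is 5/13 printed
        (0.4000, 0.8000, 0.5333),  # top-100 row
        (0.600, 0.600, 0.600),     # mean-probability row
        (5 / 13, 1.0000, 0.5556),  # max-probability row (same confusion)
    ])
    def test_published_metric_rows(self, p, r, expect):
        assert round(f1_from_pr(p, r), 4) == expect

    def test_rows_from_printed_precision_recall(self):
        """Recomputing from the 4-dp printed P/R reproduces each printed F1
        to within one unit in the last printed digit (the printed inputs are
        themselves rounded)."""
        for p, r, printed in [(0.3846, 1.000, 0.5556), (0.4000, 0.8000, 0.5333),
                              (0.600, 0.600, 0.600)]:
            assert f1_from_pr(p, r) == pytest.approx(printed, abs=1e-4)

    def test_undefined_for_zero_pr(self):
        with pytest.raises(UndefinedMetricError):
            f1_from_pr(0.0, 0.0)


class TestComputeMetrics:
    def test_hand_confusion_arithmetic(self):
        """13 patients, tp=3 fp=2 fn=2 tn=6 -> P = R = F1 = 0.6, acc 9/13."""
        truth = ["high"] * 5 + ["low"] * 8
        pred = (["high"] * 3 + ["low"] * 2) + (["high"] * 2 + ["low"] * 6)
        probs = [0.9, 0.8, 0.7, 0.4, 0.3] + [0.6, 0.55, 0.2, 0.25, 0.3, 0.1, 0.15, 0.05]
        m = compute_metrics(truth, pred, probs)
        assert (m.tp, m.fp, m.fn, m.tn) == (3, 2, 2, 6)
        assert m.precision == pytest.approx(0.600)
        assert m.recall == pytest.approx(0.600)
        assert m.f1 == pytest.approx(0.600)
        assert m.accuracy == pytest.approx(9 / 13)

    def test_perfect_separation_auc_one(self):
        m = compute_metrics(["high", "high", "low"], ["high", "high", "low"],
                            [0.9, 0.8, 0.1])
        assert m.auc == 1.0

    def test_all_tied_scores_auc_half(self):
        m = compute_metrics(["high", "low"], ["low", "low"], [0.5, 0.5])
        assert m.auc == 0.5

    def test_auc_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(4, 40)
            labels = ["high" if v else "low" for v in rng.integers(0, 2, n)]
            if "high" not in labels or "low" not in labels:
                continue
            scores = np.round(rng.uniform(0, 1, n), 2)  # rounded -> ties occur
            assert auc_rank(labels, scores) == pytest.approx(
                oracle_auc(labels, scores), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        labels = ["high" if v else "low" for v in rng.integers(0, 2, 30)]
        scores = rng.uniform(0, 1, 30)
        a = auc_rank(labels, scores)
        assert auc_rank(labels, np.exp(5 * scores)) == pytest.approx(a, abs=1e-12)

    def test_single_class_truth_flags_auc(self):
        m = compute_metrics(["high", "high"], ["high", "low"], [0.9, 0.1])
        assert np.isnan(m.auc) and any("AUC" in n for n in m.notes)


class TestPredictBags:
    def test_strategies_and_k_used(self):
        bags = {"a": np.array([0.9, 0.1]), "b": np.array([0.2, 0.3, 0.4])}
        out = predict_bags(bags, "top10")
        by_id = {p.patient_id: p for p in out}
        assert by_id["a"].k_used == 2 and by_id["b"].k_used == 3
        assert by_id["a"].bag_prob == pytest.approx(0.5)
        assert by_id["a"].predicted_label == "high"
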