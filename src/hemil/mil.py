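"""Multiple-instance bag aggregation and the evaluation metric suite.

A patient is a bag, a 224x224 patch an instance.  Four pooling strategies
turn instance probabilities into a bag probability:

* ``mean``   — arithmetic mean over all instances;
* ``top10``  — mean of the 10 largest instance probabilities;
* ``top100`` — mean of the 100 largest;
* ``max``    — the single largest.

Bags smaller than k use all their instances (``k_used = min(k, n)``), the
only convention under which top-k degenerates to the plain mean as k grows
and to max at k = 1.

AUC uses the tie-aware rank (Mann-Whitney) formulation: the probability
that a random positive bag outscores a random negative one, ties counted
half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

STRATEGY_K = {"mean": None, "top10": 10, "top100": 100, "max": 1}


class UndefinedMetricError(ValueError):
    """Raised when a requested metric has no defined value."""


@dataclass
class Bag:
    patient_id: str
    patch_ids: list[str]
    label: str  # "high" | "low"
    split: str = "train"

    def __post_init__(self) -> None:
        if not self.patch_ids:
            raise ValueError("a bag needs at least one instance")
        if len(set(self.patch_ids)) != len(self.patch_ids):
            raise ValueError("patch_ids must be unique")


@dataclass
class BagPrediction:
    patient_id: str
    strategy: str
    k_used: int
    bag_prob: float
    predicted_label: str = ""


@dataclass
class MetricsReport:
    auc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    notes: list[str] = field(default_factory=list)


def aggregate(instance_probs, strategy: str, k: int | None = None) -> float:
    """Pool instance probabilities into one bag probability."""
    probs = np.asarray(instance_probs, dtype=float)
    if probs.size == 0:
        raise ValueError("empty bag")
    if strategy == "mean":
        return float(probs.mean())
    if strategy == "max":
        return float(probs.max())
    if strategy in ("top10", "top100", "topk"):
        if strategy != "topk":
            k = STRATEGY_K[strategy]
        if k is None or k < 1:
            raise ValueError("top-k pooling needs k >= 1")
        k_used = min(k, probs.size)
        top = np.partition(probs, probs.size - k_used)[probs.size - k_used:]
        return float(top.mean())
    raise ValueError(f"unknown strategy {strategy!r}")


def k_used_for(strategy: str, n_instances: int, k: int | None = None) -> int:
    if strategy == "mean":
        return n_instances
    if strategy == "max":
        return 1
    k = STRATEGY_K.get(strategy, k) if strategy != "topk" else k
    return min(int(k), n_instances)


def predict_bags(instance_probs_by_bag: dict[str, np.ndarray], strategy: str,
                 k: int | None = None, threshold: float = 0.5) -> list[BagPrediction]:
    """Aggregate + threshold every bag under one strategy."""
    preds = []
    for pid, probs in instance_probs_by_bag.items():
        prob = aggregate(probs, strategy, k)
        preds.append(BagPrediction(
            patient_id=pid, strategy=strategy,
            k_used=k_used_for(strategy, len(np.asarray(probs)), k),
            bag_prob=prob))
    return classify_bags(preds, threshold)


def classify_bags(bag_preds: list[BagPrediction],
                  threshold: float = 0.5) -> list[BagPrediction]:
    """Label = high iff bag_prob >= threshold (boundary inclusive)."""
    for p in bag_preds:
        if not (0 <= p.bag_prob <= 1):
            raise ValueError(f"bag probability {p.bag_prob} outside [0,1]")
        p.predicted_label = "high" if p.bag_prob >= threshold else "low"
    return bag_preds


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R)."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must be in [0,1]")
    if precision == 0 and recall == 0:
        raise UndefinedMetricError("F1 undefined for P = R = 0")
    return 2 * precision * recall / (precision + recall)


def auc_rank(labels, scores) -> float:
    """Tie-aware rank AUC: P(score_pos > score_neg) + 0.5*P(equal)."""
    y = np.asarray([1 if lab == "high" else 0 for lab in labels])
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined with a single class")
    ranks = rankdata(s)  # average ranks handle ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(true_labels, predicted_labels, bag_probs) -> MetricsReport:
    """Confusion-based metrics plus rank AUC; "high" is the positive class."""
    t = list(true_labels)
    p = list(predicted_labels)
    s = list(bag_probs)
    if not (len(t) == len(p) == len(s)) or len(t) == 0:
        raise ValueError("labels, predictions and scores must have equal length >= 1")
    tp = sum(1 for a, b in zip(t, p) if a == "high" and b == "high")
    fp = sum(1 for a, b in zip(t, p) if a == "low" and b == "high")
    fn = sum(1 for a, b in zip(t, p) if a == "high" and b == "low")
    tn = sum(1 for a, b in zip(t, p) if a == "low" and b == "low")
    notes = []
    accuracy = (tp + tn) / len(t)
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    if precision == 0 and recall == 0 or np.isnan(precision) or np.isnan(recall):
        f1 = float("nan")
        notes.append("F1 undefined")
    else:
        f1 = f1_from_pr(precision, recall)
    try:
        auc = auc_rank(t, s)
    except UndefinedMetricError:
        auc = float("nan")
        notes.append("AUC undefined: single-class truth")
    return MetricsReport(auc=auc, accuracy=accuracy, precision=precision,
                         recall=recall, f1=f1, tp=tp, fp=fp, fn=fn, tn=tn,
                         notes=notes)
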