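"""Predictor evaluation: MCC, ROC/AROC, best-threshold MCC, paired AROC
bootstrap comparison, and the summary statistics used when reporting a
target-selection pipeline (multi-stage accuracy product, success rate).

Conventions, pinned so the threshold-sweep and rank formulations of AROC
agree exactly:

* AROC ties get half credit (Mann–Whitney convention).
* MCC with a zero factor in its denominator is 0.
* Thresholds classify as positive when ``score >= threshold``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import EvaluationError


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise EvaluationError("confusion table is empty")


@dataclasses.dataclass(frozen=True)
class RocCurve:
    """ROC points from (0,0) to (1,1) with trapezoidal area."""

    points: np.ndarray          # k x 2 array of (fpr, tpr)
    auc: float
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["fpr", "tpr"])


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _check_two_class(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("evaluation needs both classes present")
    return n_pos, n_neg


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    # Mann-Whitney U with ties counted 1/2, via midranks
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve over descending score thresholds (tied scores = one step).

    The area equals both the trapezoidal integral of the curve and the
    tie-corrected rank statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise EvaluationError("scores and labels must have equal length")
    n_pos, n_neg = _check_two_class(labels)
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=points, auc=auc, n_pos=n_pos, n_neg=n_neg)


def best_mcc(scores: Sequence[float],
             labels: Sequence[int]) -> tuple[float, float]:
    """(threshold, MCC) maximising MCC over all achievable cuts.

    Candidate thresholds are midpoints between adjacent distinct scores
    plus -inf/+inf; ties in MCC resolve to the lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise EvaluationError("scores and labels must have equal length")
    n_pos, n_neg = _check_two_class(labels)

    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    distinct = np.unique(s_sorted)
    cuts = np.concatenate([[-np.inf],
                           0.5 * (distinct[:-1] + distinct[1:]),
                           [np.inf]])
    # predicted positive <=> score >= cut; counts via cumulative label sums
    pos_below = np.concatenate([[0], np.cumsum(l_sorted)])
    neg_below = np.concatenate([[0], np.cumsum(1 - l_sorted)])
    idx = np.searchsorted(s_sorted, cuts, side="left")
    fn = pos_below[idx]
    tn = neg_below[idx]
    tp = n_pos - fn
    fp = n_neg - tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (tp * tn - fp * fn) / np.sqrt(denom.astype(float))
    vals = np.where(denom == 0, 0.0, vals)
    best = int(np.argmax(vals))          # first max = lowest threshold
    return float(cuts[best]), float(vals[best])


def compare_auc(scores_a: Sequence[float], scores_b: Sequence[float],
                labels: Sequence[int], n_boot: int = 2000,
                seed: int | np.random.Generator | None = None) -> float:
    """Two-tailed p-value for a paired AROC difference, by stratified bootstrap.

    Both score vectors must be paired on the same instances. Instances are
    resampled with replacement within each class; the p-value is
    ``2 * min(P(diff <= 0), P(diff >= 0))`` with the (count+1)/(n_boot+1)
    small-sample correction, capped at 1. Deterministic given a seed.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (a.shape == b.shape == labels.shape):
        raise EvaluationError("paired scores and labels must share length")
    _check_two_class(labels)
    if n_boot < 100:
        raise EvaluationError("n_boot must be >= 100")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    le = ge = 0
    for _ in range(n_boot):
        p = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        n = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        take = np.concatenate([p, n])
        lab = np.concatenate([np.ones(p.size, dtype=int),
                              np.zeros(n.size, dtype=int)])
        diff = _auc_rank(a[take], lab) - _auc_rank(b[take], lab)
        if diff <= 0:
            le += 1
        if diff >= 0:
            ge += 1
    p_val = 2.0 * min((le + 1) / (n_boot + 1), (ge + 1) / (n_boot + 1))
    return min(p_val, 1.0)


def combined_stage_accuracy(stage_accuracies: Sequence[float]) -> float:
    """Accuracy of passing every stage, assuming independent stage errors.

    The product argument is why a single whole-pipeline predictor beats a
    chain of per-stage predictors: two 75%-accurate stages compound to
    only 56% for the full route.
    """
    if len(stage_accuracies) == 0:
        raise EvaluationError("need at least one stage accuracy")
    out = 1.0
    for a in stage_accuracies:
        if not 0.0 <= a <= 1.0:
            raise EvaluationError(f"accuracy {a} outside [0, 1]")
        out *= a
    return out


def success_rate(successes: int, attempts: int) -> float:
    """Percentage of attempts that succeeded (0-100)."""
    if attempts < 1 or not 0 <= successes <= attempts:
        raise EvaluationError(
            f"need 0 <= successes <= attempts >= 1, got {successes}/{attempts}")
    return 100.0 * successes / attempts


def as_integer_percent(fraction_or_percent: float, *,
                       is_fraction: bool = False) -> int:
    """Round-half-away-from-zero integer percent presentation."""
    value = fraction_or_percent * 100.0 if is_fraction else fraction_or_percent
    return int(math.floor(value + 0.5)) if value >= 0 else int(math.ceil(value - 0.5))


def confusion_at_threshold(scores: Sequence[float], labels: Sequence[int],
                           threshold: float) -> ConfusionCounts:
    """Confusion table for the rule score >= threshold -> positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
        fp=int(np.sum(pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


def write_roc_tsv(curve: RocCurve, path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def plot_roc(curves: dict[str, RocCurve], path) -> None:
    """Plot one or more ROC curves (labelled with their AROC) to an image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, curve in curves.items():
        ax.plot(curve.points[:, 0], curve.points[:, 1],
                label=f"{name} (AROC {curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
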