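"""Validation machinery: Tm-Tagg class labels, ROC/AUC, MCC, Pearson.

Antibodies that start aggregating well below their melting transition
(Tm - Tagg above a cutoff, default 5 °C) aggregate from the native state and
form the positive class; the Solubis score is evaluated as a classifier of
that label and as a correlate of the Tm - Tagg gap itself.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats


@dataclasses.dataclass
class EvalRecord:
    antibody: str
    solubis_score: float
    total_tango: float | None = None
    n_aprs: int | None = None
    t_m: float | None = None    # °C
    t_agg: float | None = None  # °C
    gap: float | None = None    # Tm - Tagg, °C
    label: int | None = None

    def __post_init__(self) -> None:
        if self.gap is None and self.t_m is not None and self.t_agg is not None:
            self.gap = self.t_m - self.t_agg


def label_records(
    records: list[EvalRecord],
    gap_cutoff: float = 5.0,
    forced: dict[str, int] | None = None,
) -> list[EvalRecord]:
    """Assign class labels: 1 iff gap > cutoff (strict); explicit overrides win."""
    forced = forced or {}
    for r in records:
        if r.antibody in forced:
            r.label = int(forced[r.antibody])
        elif r.gap is not None:
            r.label = int(r.gap > gap_cutoff)
        else:
            raise ValueError(f"record {r.antibody} has neither a gap nor a forced label")
    return records


def _check_two_classes(labels) -> None:
    labels = np.asarray(labels)
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("need at least one positive and one negative label")


def roc_curve(scores, labels) -> tuple[list[tuple[float, float, float]], float]:
    """ROC points (threshold, TPR, FPR) at every distinct score, plus AUC.

    A record is predicted positive when its score >= threshold.  The AUC is
    the Mann-Whitney pair-counting statistic: the fraction of
    (positive, negative) score pairs ranked correctly, ties counting 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    points = []
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    for t in thresholds:
        tpr = float(np.mean(pos >= t))
        fpr = float(np.mean(neg >= t))
        points.append((float(t), tpr, fpr))
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    auc = float((gt + 0.5 * eq) / (len(pos) * len(neg)))
    return points, auc


def mcc(scores, labels, threshold: float) -> float:
    """Matthews correlation coefficient at a score threshold (>= = positive).

    Returns 0 when any marginal of the confusion table is empty (degenerate
    denominator convention).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def pearson(x, y) -> float:
    """Product-moment correlation; requires length >= 3 and nonzero variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson requires two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson is undefined for zero-variance input")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def best_mcc_threshold(scores, labels) -> tuple[float, float]:
    """The score threshold maximising MCC (ties: lowest threshold), and its MCC."""
    scores = np.asarray(scores, dtype=float)
    best_t, best_m = None, -2.0
    for t in np.unique(scores):
        m = mcc(scores, labels, t)
        if m > best_m:
            best_t, best_m = float(t), m
    return best_t, best_m


def evaluate_records(
    records: list[EvalRecord],
    gap_cutoff: float = 5.0,
    forced: dict[str, int] | None = None,
) -> dict:
    """Full evaluation: labels, ROC/AUC, best-threshold MCC, Pearson vs gap."""
    label_records(records, gap_cutoff, forced)
    scores = [r.solubis_score for r in records]
    labels = [r.label for r in records]
    points, auc = roc_curve(scores, labels)
    threshold, best_m = best_mcc_threshold(scores, labels)
    with_gap = [r for r in records if r.gap is not None]
    r_p = (
        pearson([r.solubis_score for r in with_gap], [r.gap for r in with_gap])
        if len(with_gap) >= 3
        else None
    )
    return {
        "auc": auc,
        "mcc": best_m,
        "threshold": threshold,
        "pearson": r_p,
        "n_records": len(records),
        "gap_cutoff": gap_cutoff,
        "roc": points,
    }
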