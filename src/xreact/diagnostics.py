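"""Similarity as a diagnostic test for cross-reactivity.

Treats the Tanimoto score as the output of a screening test and the
empirical cross-reactivity label as truth: confusion counts at a cutoff,
sensitivity / specificity / efficiency, the ROC curve with its AUC, and
the cutoff maximizing efficiency.

Definitions (the clinical-chemistry conventions):

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    efficiency  = (TP + TN) / (TP + TN + FP + FN)

A compound is predicted positive when its score is **>= cutoff** (so the
calibrator itself, at similarity 1.0, stays positive at any cutoff).
ROC analysis refuses to run with fewer than five compounds in either
class: with so few datapoints the curve invites over-interpretation, the
same guard the reference evaluation software applies.

AUC is computed two ways — trapezoidal integration of the empirical curve
and the tie-corrected Mann–Whitney pair statistic — and the two are
asserted equal; they are mathematically identical when the curve is built
at every observed score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panels import CROSS_REACTIVE, NON_CROSS_REACTIVE

LABELS = {CROSS_REACTIVE, NON_CROSS_REACTIVE}


class ClassSizeError(ValueError):
    """ROC analysis refused: too few compounds in one of the classes."""

    def __init__(self, n_positive: int, n_negative: int, min_class_size: int):
        self.n_positive = n_positive
        self.n_negative = n_negative
        self.min_class_size = min_class_size
        super().__init__(
            f"ROC analysis requires at least {min_class_size} compounds per class; "
            f"got {n_positive} cross-reactive and {n_negative} non-cross-reactive"
        )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class DiagnosticMetrics:
    """The three ratios; a zero-denominator metric is NaN and listed in
    ``undefined`` rather than silently reported as 0."""

    sensitivity: float
    specificity: float
    efficiency: float
    undefined: tuple[str, ...] = ()


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    counts: ConfusionCounts
    metrics: DiagnosticMetrics


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _validate_table(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if table.empty:
        raise ValueError("score/label table is empty")
    bad = set(table["label"]) - LABELS
    if bad:
        raise ValueError(f"non-binary labels {sorted(bad)}; expected {sorted(LABELS)}")
    scores = table["score"].to_numpy(dtype=float)
    positive = (table["label"] == CROSS_REACTIVE).to_numpy()
    return scores, positive


def confusion_at_cutoff(table: pd.DataFrame, cutoff: float) -> ConfusionCounts:
    """Confusion counts with "predicted positive iff score >= cutoff"."""
    scores, positive = _validate_table(table)
    pred = scores >= cutoff
    return ConfusionCounts(
        tp=int((pred & positive).sum()),
        fp=int((pred & ~positive).sum()),
        tn=int((~pred & ~positive).sum()),
        fn=int((~pred & positive).sum()),
        cutoff=float(cutoff),
    )


def metrics(counts: ConfusionCounts) -> DiagnosticMetrics:
    """Sensitivity, specificity and efficiency from confusion counts."""
    undefined = []
    if counts.n_positive > 0:
        sens = counts.tp / counts.n_positive
    else:
        sens, undefined = math.nan, undefined + ["sensitivity"]
    if counts.n_negative > 0:
        spec = counts.tn / counts.n_negative
    else:
        spec, undefined = math.nan, undefined + ["specificity"]
    total = counts.n_positive + counts.n_negative
    if total > 0:
        eff = (counts.tp + counts.tn) / total
    else:
        eff, undefined = math.nan, undefined + ["efficiency"]
    return DiagnosticMetrics(sens, spec, eff, tuple(undefined))


def _check_class_sizes(positive: np.ndarray, min_class_size: int) -> None:
    n_pos, n_neg = int(positive.sum()), int((~positive).sum())
    if n_pos < min_class_size or n_neg < min_class_size:
        raise ClassSizeError(n_pos, n_neg, min_class_size)


def mann_whitney_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUC as the tie-corrected probability that a random positive scores
    above a random negative (ties count half)."""
    pos = scores[positive]
    neg = scores[~positive]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(pos) * len(neg)))


def roc_curve(table: pd.DataFrame, min_class_size: int = 5) -> RocCurve:
    """Empirical ROC curve over every observed score plus sentinels.

    Thresholds descend from above the maximum score (point (0,0)) through
    each distinct observed score to below the minimum (point (1,1)); each
    point is the (FPR, TPR) of ``confusion_at_cutoff`` at that threshold.
    AUC is the trapezoidal area, asserted equal to the Mann–Whitney pair
    statistic.
    """
    scores, positive = _validate_table(table)
    _check_class_sizes(positive, min_class_size)

    distinct = np.unique(scores)[::-1]  # descending
    hi = distinct[0] + 1.0
    lo = distinct[-1] - 1.0
    thresholds = np.concatenate(([hi], distinct, [lo]))

    n_pos = positive.sum()
    n_neg = (~positive).sum()
    tpr, fpr = [], []
    for t in thresholds:
        pred = scores >= t
        tpr.append((pred & positive).sum() / n_pos)
        fpr.append((pred & ~positive).sum() / n_neg)
    fpr_a, tpr_a = np.asarray(fpr), np.asarray(tpr)
    auc = float(np.trapezoid(tpr_a, fpr_a))
    mw = mann_whitney_auc(scores, positive)
    assert abs(auc - mw) < 1e-12, f"trapezoid {auc} != Mann-Whitney {mw}"
    return RocCurve(fpr=fpr_a, tpr=tpr_a, thresholds=thresholds, auc=auc)


def candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus sentinels below the
    minimum and above the maximum."""
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([distinct[0] - 0.5], mids, [distinct[-1] + 0.5]))


def max_efficiency_cutoff(table: pd.DataFrame, min_class_size: int = 5) -> CutoffResult:
    """The candidate cutoff maximizing efficiency.

    Ties are broken toward higher specificity, then toward the higher
    cutoff — a screening-oriented preference for fewer false positives.
    """
    scores, positive = _validate_table(table)
    _check_class_sizes(positive, min_class_size)
    best: CutoffResult | None = None
    for c in candidate_cutoffs(scores):
        counts = confusion_at_cutoff(table, float(c))
        m = metrics(counts)
        key = (m.efficiency, m.specificity, c)
        if best is None or key > (best.metrics.efficiency, best.metrics.specificity, best.cutoff):
            best = CutoffResult(float(c), counts, m)
    return best


def predict(
    untested: pd.DataFrame,
    cutoff: float,
    assay_name: str = "",
    key_set_id: str = "",
) -> pd.DataFrame:
    """Predicted labels for untested compounds at a chosen cutoff.

    Output carries score, cutoff, assay and key-table id so every
    prediction is traceable to the table and threshold that produced it.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    out = untested.copy()
    out["predicted"] = np.where(
        out["score"] >= cutoff if len(out) else [], CROSS_REACTIVE, NON_CROSS_REACTIVE
    )
    out["cutoff"] = cutoff
    out["assay"] = assay_name
    out["key_set_id"] = key_set_id
    return out
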