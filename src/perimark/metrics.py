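"""Classifier performance: confusion counts, sensitivity/specificity,
ROC-AUC from a 5%-interval threshold sweep, rank scores and performance
classes.

Peri-implantitis (PI) is the positive class throughout. Sensitivity is
TP/(TP+FN), specificity TN/(TN+FP). The ROC curve is built by sweeping a
decision threshold over the observed score range at 5% steps (21 thresholds
from the minimum to the maximum score, plus open endpoints), classifying
``score > threshold`` as PI, and integrating the resulting (FPR, TPR)
points with the trapezoidal rule. Models are ranked by
``100 * (sensitivity + specificity + AUC)`` and binned into performance
classes by the weaker of sensitivity and specificity:
poor < 70% <= reasonable < 80% <= good < 90% <= excellent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError, ValidationError
from .io import CohortLabels

PERFORMANCE_CLASSES = ("poor", "reasonable", "good", "excellent")


@dataclass
class ConfusionCounts:
    """2x2 confusion counts with PI as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predictions: pd.Series, labels: CohortLabels) -> ConfusionCounts:
    """Tally predictions (HI/PI per sample) against true labels."""
    predictions = pd.Series(predictions)
    truth = labels.labels
    missing = [s for s in predictions.index if s not in truth.index]
    if missing:
        raise ValidationError(f"predictions for unlabeled samples: {missing}")
    truth = truth.loc[predictions.index]
    bad = set(predictions.unique()) - {"HI", "PI"}
    if bad:
        raise ValidationError(f"predictions must be HI or PI, got {sorted(bad)}")
    pred_pi = (predictions == "PI").to_numpy()
    true_pi = (truth == "PI").to_numpy()
    return ConfusionCounts(
        tp=int((pred_pi & true_pi).sum()),
        fp=int((pred_pi & ~true_pi).sum()),
        tn=int((~pred_pi & ~true_pi).sum()),
        fn=int((~pred_pi & true_pi).sum()),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """True-positive rate TP/(TP+FN)."""
    denom = c.tp + c.fn
    if denom == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive samples")
    return c.tp / denom


def specificity(c: ConfusionCounts) -> float:
    """True-negative rate TN/(TN+FP)."""
    denom = c.tn + c.fp
    if denom == 0:
        raise UndefinedMetricError("specificity undefined: no negative samples")
    return c.tn / denom


def roc_auc(
    scores: pd.Series,
    labels: CohortLabels,
    interval: float | None = 5.0,
) -> tuple[list[tuple[float, float]], float]:
    """ROC points and AUC from a threshold sweep over the score range.

    Thresholds sit at ``interval``-percent steps of the observed score
    range (the default 5% gives 21 interior thresholds), bracketed by open
    endpoints so the curve always spans (0,0) to (1,1). ``interval=None``
    sweeps every distinct score instead (the all-thresholds limit, in which
    the trapezoidal AUC equals the Mann-Whitney statistic U/(n1*n2)).
    A sample counts as predicted PI when its score strictly exceeds the
    threshold; higher scores must mean more PI-like.
    """
    scores = pd.Series(scores).astype(float)
    if not np.isfinite(scores.to_numpy()).all():
        raise ValidationError("scores must be finite")
    truth = labels.labels.loc[scores.index]
    true_pi = (truth == "PI").to_numpy()
    n_pi = int(true_pi.sum())
    n_hi = int((~true_pi).sum())
    if n_pi == 0 or n_hi == 0:
        raise ValidationError("both classes must be present for a ROC curve")

    s = scores.to_numpy()
    lo, hi = s.min(), s.max()
    if interval is None:
        thresholds = np.unique(s)
    else:
        if not 0 < interval <= 100:
            raise ValidationError("interval must be a percentage in (0, 100]")
        n_steps = int(round(100.0 / interval))
        thresholds = lo + (hi - lo) * np.arange(n_steps + 1) / n_steps
    # open endpoints: everything predicted PI / nothing predicted PI
    thresholds = np.concatenate([[-np.inf], thresholds, [np.inf]])

    pred = s[None, :] > thresholds[:, None]  # (n_thresholds, n_samples)
    tpr = pred[:, true_pi].sum(axis=1) / n_pi
    fpr = pred[:, ~true_pi].sum(axis=1) / n_hi
    order = np.lexsort((tpr, fpr))  # ascending FPR, then TPR
    fpr, tpr = fpr[order], tpr[order]
    points = list(dict.fromkeys(zip(fpr.tolist(), tpr.tolist())))
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


@dataclass
class PerformanceReport:
    """Summary of one classifier's performance on one sample set."""

    sensitivity: float
    specificity: float
    auc: float
    roc_points: list = field(default_factory=list)
    model_id: str | None = None

    @property
    def rank_score(self) -> float:
        """100 * (sensitivity + specificity + AUC) — the model-ranking score."""
        return 100.0 * (self.sensitivity + self.specificity + self.auc)

    @property
    def performance_class(self) -> str:
        return classify_performance(self)


def classify_performance(report: PerformanceReport) -> str:
    """Bin a report by the weaker of sensitivity and specificity.

    poor < 0.70 <= reasonable < 0.80 <= good < 0.90 <= excellent.
    """
    weaker = min(report.sensitivity, report.specificity)
    if weaker < 0.70:
        return "poor"
    if weaker < 0.80:
        return "reasonable"
    if weaker < 0.90:
        return "good"
    return "excellent"


def rank_models(reports: list[PerformanceReport]) -> list[PerformanceReport]:
    """Order reports by rank score, descending; deterministic and stable.

    Ties break by sensitivity, then specificity, then model id (None last),
    then original position.
    """
    if not reports:
        raise ValidationError("cannot rank an empty list of reports")

    def key(item):
        i, r = item
        return (
            -r.rank_score,
            -r.sensitivity,
            -r.specificity,
            (r.model_id is None, r.model_id or ""),
            i,
        )

    return [r for _, r in sorted(enumerate(reports), key=key)]


def evaluate_scores(
    scores: pd.Series,
    predictions: pd.Series,
    labels: CohortLabels,
    interval: float | None = 5.0,
    model_id: str | None = None,
) -> PerformanceReport:
    """Build a full report from continuous scores plus binary predictions."""
    c = confusion(predictions, labels)
    points, auc = roc_auc(scores, labels, interval=interval)
    return PerformanceReport(
        sensitivity=sensitivity(c),
        specificity=specificity(c),
        auc=auc,
        roc_points=points,
        model_id=model_id,
    )
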