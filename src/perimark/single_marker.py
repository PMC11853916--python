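"""Single-microorganism cutoff classifiers.

One taxon, one direction, one abundance cutoff: if the taxon is on average
more abundant in peri-implantitis (PI) than in healthy implants (HI), the
classifier predicts PI when the sample's abundance strictly exceeds the
cutoff; if less abundant, it predicts PI when the abundance is strictly
below the cutoff. Values exactly at the cutoff predict HI.

The cutoff is chosen over candidates at midpoints between consecutive
sorted unique training abundances plus the two extremes, maximizing
training sensitivity. Because the extreme cutoff trivially reaches
sensitivity 1, ties are broken by maximal specificity, then by the cutoff
farthest from the PI-group extreme (the most conservative boundary), then
by the smallest cutoff — making the optimum well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import AbundanceTable, CohortLabels
from .screening import HIGHER_IN_PI, LOWER_IN_PI


@dataclass
class SingleMarkerModel:
    """A fitted one-taxon cutoff classifier."""

    taxon_id: str
    direction: str  # higher_in_PI or lower_in_PI
    cutoff: float  # ppm
    train_sensitivity: float | None = None
    train_specificity: float | None = None
    degenerate: bool = False


def candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive sorted unique values, plus both extremes."""
    uniq = np.unique(values)
    if uniq.size == 1:
        return uniq
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[uniq[0]], mids, [uniq[-1]]])


def _sens_spec_at(cutoff: float, direction: str, pi: np.ndarray, hi: np.ndarray):
    if direction == HIGHER_IN_PI:
        sens = float(np.mean(pi > cutoff))
        spec = float(np.mean(hi <= cutoff))
    else:
        sens = float(np.mean(pi < cutoff))
        spec = float(np.mean(hi >= cutoff))
    return sens, spec


def fit_single_marker(
    table: AbundanceTable, labels: CohortLabels, taxon_id
) -> SingleMarkerModel:
    """Fit the direction and sensitivity-optimal cutoff for one taxon.

    Direction comes from the group-mean comparison (mean ties default to
    ``higher_in_PI``). All training samples are used; the search is an
    exhaustive scan of the candidate cutoffs.
    """
    series = table.values_for(taxon_id)  # KeyError when absent
    aligned = labels.align_with(table)
    pi = series[(aligned == "PI").to_numpy()].to_numpy()
    hi = series[(aligned == "HI").to_numpy()].to_numpy()
    if pi.size == 0 or hi.size == 0:
        raise ValidationError("both groups must be non-empty to fit a marker")

    values = series.to_numpy()
    if np.ptp(values) == 0:
        warnings.warn(
            f"taxon {taxon_id!r} has identical abundance in every sample; "
            "degenerate marker",
            stacklevel=2,
        )
        cutoff = float(values[0])
        sens, spec = _sens_spec_at(cutoff, HIGHER_IN_PI, pi, hi)
        return SingleMarkerModel(
            taxon_id, HIGHER_IN_PI, cutoff, sens, spec, degenerate=True
        )

    direction = HIGHER_IN_PI if pi.mean() >= hi.mean() else LOWER_IN_PI
    pi_extreme = pi.min() if direction == HIGHER_IN_PI else pi.max()

    best = None
    for cut in candidate_cutoffs(values):
        sens, spec = _sens_spec_at(cut, direction, pi, hi)
        key = (sens, spec, abs(cut - pi_extreme), -cut)
        if best is None or key > best[0]:
            best = (key, float(cut), sens, spec)
    _, cutoff, sens, spec = best
    return SingleMarkerModel(taxon_id, direction, cutoff, sens, spec)


def marker_scores(model: SingleMarkerModel, table: AbundanceTable) -> pd.Series:
    """Continuous PI-leaning score underlying the binary rule.

    Equal to the abundance for ``higher_in_PI`` markers and its negation
    for ``lower_in_PI`` markers, so that larger always means more PI-like
    (used for ROC sweeps).
    """
    series = table.values_for(model.taxon_id)
    return series if model.direction == HIGHER_IN_PI else -series


def predict_single_marker(model: SingleMarkerModel, table: AbundanceTable) -> pd.Series:
    """Apply the direction/cutoff rule; returns a per-sample HI/PI Series."""
    series = table.values_for(model.taxon_id)
    if model.direction == HIGHER_IN_PI:
        is_pi = series > model.cutoff
    elif model.direction == LOWER_IN_PI:
        is_pi = series < model.cutoff
    else:
        raise ValidationError(f"unknown direction {model.direction!r}")
    return pd.Series(np.where(is_pi, "PI", "HI"), index=series.index)
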