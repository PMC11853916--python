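"""Combination-scoring classifiers over 2-4 taxon biomarker panels.

A fitted panel stores, for each member taxon *i*, the training-group
medians ``median_PI_i`` and ``median_HI_i`` and an enrichment weight
``W_i`` in [0, 1]. A sample with abundance ``x_i`` scores

    S = sum_i 100 * W_i * (N_i - P_i) / (P_i + N_i)

where ``P_i = |median_PI_i - x_i|`` and ``N_i = |median_HI_i - x_i|`` are
the absolute distances to the peri-implantitis (PI) and healthy-implant
(HI) medians. Each term lies in ``[-100*W_i, +100*W_i]``: positive when
the sample sits nearer the PI median, negative when nearer the HI median,
and zero in the degenerate case ``P_i = N_i = 0`` (both medians coincide
with the value). The classifier predicts PI when ``S`` strictly exceeds a
decision threshold tau (default 0, i.e. the score's sign).

``W_i`` is a pseudocounted presence-frequency enrichment,
``(f_PI + eps) / (f_PI + f_HI + 2*eps)`` with ``f_G`` the fraction of
group-G training samples in which the taxon is detected (nonzero) and
``eps`` a continuity pseudocount; a mean-abundance-ratio variant is
available via ``weight_scheme="abundance_ratio"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import AbundanceTable, CohortLabels

MIN_PANEL = 2
MAX_PANEL = 4

WEIGHT_SCHEMES = ("presence", "abundance_ratio")


@dataclass
class ComboScoreModel:
    """A fitted biomarker-panel scoring classifier."""

    taxa: tuple
    median_pi: np.ndarray  # per-taxon PI-group training medians (ppm)
    median_hi: np.ndarray  # per-taxon HI-group training medians (ppm)
    weights: np.ndarray  # per-taxon enrichment weights in [0, 1]
    threshold: float = 0.0  # decision threshold tau on the score S
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("panel taxa must be distinct")
        self.median_pi = np.asarray(self.median_pi, dtype=float)
        self.median_hi = np.asarray(self.median_hi, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.taxa)
        for name, arr in (
            ("median_pi", self.median_pi),
            ("median_hi", self.median_hi),
            ("weights", self.weights),
        ):
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have one entry per panel taxon")
            if not np.isfinite(arr).all():
                raise ValidationError(f"{name} must be finite")
        if (self.median_pi < 0).any() or (self.median_hi < 0).any():
            raise ValidationError("medians must be non-negative")
        if ((self.weights < 0) | (self.weights > 1)).any():
            raise ValidationError("weights must lie in [0, 1]")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def to_json(self, path=None) -> str:
        doc = {
            "taxa": list(self.taxa),
            "median_pi": self.median_pi.tolist(),
            "median_hi": self.median_hi.tolist(),
            "weights": self.weights.tolist(),
            "threshold": self.threshold,
            "metadata": self.metadata,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ComboScoreModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            taxa=tuple(doc["taxa"]),
            median_pi=doc["median_pi"],
            median_hi=doc["median_hi"],
            weights=doc["weights"],
            threshold=doc["threshold"],
            metadata=doc.get("metadata", {}),
        )


def score_terms(model: ComboScoreModel, values: np.ndarray) -> np.ndarray:
    """Per-taxon score terms for an (n_samples, n_taxa) abundance block."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    p = np.abs(model.median_pi[None, :] - values)
    n = np.abs(model.median_hi[None, :] - values)
    denom = p + n
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = 100.0 * model.weights[None, :] * (n - p) / denom
    terms[denom == 0] = 0.0  # sample exactly at coinciding medians
    return terms


def combo_score(model: ComboScoreModel, sample) -> float:
    """Eq.-style panel score S for a single sample.

    ``sample`` may be a mapping/Series of taxon -> abundance or a plain
    sequence ordered like ``model.taxa``.
    """
    if isinstance(sample, (pd.Series, dict)):
        try:
            values = np.array([sample[t] for t in model.taxa], dtype=float)
        except KeyError as exc:
            raise ValidationError(f"sample is missing taxon {exc.args[0]!r}") from exc
    else:
        values = np.asarray(sample, dtype=float)
        if values.shape != (model.n_taxa,):
            raise ValidationError(
                f"expected {model.n_taxa} abundances, got shape {values.shape}"
            )
    if not np.isfinite(values).all():
        raise ValidationError("sample abundances must be finite")
    return float(score_terms(model, values[None, :]).sum())


def score_samples(model: ComboScoreModel, table: AbundanceTable) -> pd.Series:
    """Score S for every sample of a table."""
    missing = [t for t in model.taxa if t not in table.data.columns]
    if missing:
        raise ValidationError(f"table is missing panel taxa: {missing}")
    block = table.data[list(model.taxa)].to_numpy()
    return pd.Series(score_terms(model, block).sum(axis=1), index=table.data.index)


def presence_weights(
    pi_block: np.ndarray, hi_block: np.ndarray, taxa: Sequence
) -> np.ndarray:
    """Pseudocounted presence-frequency enrichment weights.

    ``W = (f_PI + eps_PI) / (f_PI + f_HI + eps_PI + eps_HI)`` with ``f_G``
    the detected (nonzero) fraction in group G and ``eps_G = 0.5 / |G|``
    half-a-sample's worth of pseudocount. A taxon detected in no training
    sample of either group carries no signal and gets W = 0.5 (warned).
    """
    n_pi, n_hi = pi_block.shape[0], hi_block.shape[0]
    f_pi = (pi_block > 0).mean(axis=0)
    f_hi = (hi_block > 0).mean(axis=0)
    eps_pi, eps_hi = 0.5 / n_pi, 0.5 / n_hi
    w = (f_pi + eps_pi) / (f_pi + f_hi + eps_pi + eps_hi)
    all_zero = (f_pi == 0) & (f_hi == 0)
    if all_zero.any():
        dead = [t for t, z in zip(taxa, all_zero) if z]
        warnings.warn(
            f"taxa with all-zero training abundance in both groups: {dead}; "
            "weight set to 0.5",
            stacklevel=2,
        )
        w = np.where(all_zero, 0.5, w)
    return w


def abundance_ratio_weights(pi_block: np.ndarray, hi_block: np.ndarray) -> np.ndarray:
    """Mean-abundance-ratio enrichment: mean_PI / (mean_PI + mean_HI)."""
    m_pi = pi_block.mean(axis=0)
    m_hi = hi_block.mean(axis=0)
    denom = m_pi + m_hi
    return np.where(denom > 0, m_pi / np.where(denom > 0, denom, 1.0), 0.5)


def tune_threshold(scores: np.ndarray, is_pi: np.ndarray) -> float:
    """Training threshold maximizing min(sensitivity, specificity).

    Candidates are the midpoints between consecutive sorted unique training
    scores together with 0; whenever 0 attains the maximum the default
    tau = 0 is kept. Remaining ties prefer larger sens+spec, then the
    threshold closest to 0 (and the smaller of two equidistant ones).
    """
    scores = np.asarray(scores, dtype=float)
    is_pi = np.asarray(is_pi, dtype=bool)
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    candidates = np.concatenate([mids, [0.0]])
    pred_pi = scores[None, :] > candidates[:, None]
    sens = pred_pi[:, is_pi].sum(axis=1) / is_pi.sum()
    spec = (~pred_pi)[:, ~is_pi].sum(axis=1) / (~is_pi).sum()
    mins = np.minimum(sens, spec)
    best_key, best_tau = None, 0.0
    for i in np.flatnonzero(mins == mins.max()):
        tau = float(candidates[i])
        key = (tau == 0.0, sens[i] + spec[i], -abs(tau), -tau)
        if best_key is None or key > best_key:
            best_key, best_tau = key, tau
    return best_tau


def fit_combo_model(
    table: AbundanceTable,
    labels: CohortLabels,
    taxa: Sequence,
    train_samples: Optional[Sequence] = None,
    weight_scheme: str = "presence",
    tune: bool = True,
    panel_size_range: tuple = (MIN_PANEL, MAX_PANEL),
) -> ComboScoreModel:
    """Fit medians, enrichment weights and the decision threshold for a panel.

    All statistics come from ``train_samples`` only (default: every
    labeled sample, matching whole-cohort fitting); held-out samples never
    touch the medians or weights.
    """
    taxa = tuple(taxa)
    lo, hi = panel_size_range
    if not lo <= len(taxa) <= hi:
        raise ValidationError(f"panel size must be in [{lo}, {hi}], got {len(taxa)}")
    if len(set(taxa)) != len(taxa):
        raise ValidationError("panel taxa must be distinct")
    missing = [t for t in taxa if t not in table.data.columns]
    if missing:
        raise ValidationError(f"table is missing panel taxa: {missing}")
    if weight_scheme not in WEIGHT_SCHEMES:
        raise ValidationError(f"weight_scheme must be one of {WEIGHT_SCHEMES}")

    if train_samples is None:
        train_samples = table.sample_ids
    train_samples = list(train_samples)
    sub = table.data.loc[train_samples, list(taxa)]
    groups = labels.labels.loc[train_samples]
    pi_block = sub[(groups == "PI").to_numpy()].to_numpy()
    hi_block = sub[(groups == "HI").to_numpy()].to_numpy()
    if pi_block.shape[0] == 0 or hi_block.shape[0] == 0:
        raise ValidationError("training samples must contain both groups")

    median_pi = np.median(pi_block, axis=0)
    median_hi = np.median(hi_block, axis=0)
    if weight_scheme == "presence":
        weights = presence_weights(pi_block, hi_block, taxa)
    else:
        weights = abundance_ratio_weights(pi_block, hi_block)

    model = ComboScoreModel(
        taxa=taxa,
        median_pi=median_pi,
        median_hi=median_hi,
        weights=weights,
        threshold=0.0,
        metadata={
            "train_samples": train_samples,
            "weight_scheme": weight_scheme,
            "n_train_pi": int(pi_block.shape[0]),
            "n_train_hi": int(hi_block.shape[0]),
        },
    )
    if tune:
        train_scores = score_terms(model, sub.to_numpy()).sum(axis=1)
        model.threshold = tune_threshold(
            train_scores, (groups == "PI").to_numpy()
        )
    return model


def predict_combo(model: ComboScoreModel, table: AbundanceTable) -> pd.Series:
    """Predict PI where S strictly exceeds the threshold, HI otherwise."""
    s = score_samples(model, table)
    return pd.Series(np.where(s > model.threshold, "PI", "HI"), index=s.index)
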