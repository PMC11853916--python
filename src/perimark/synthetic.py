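"""Synthetic labeled microbiome cohorts for end-to-end testing.

Real peri-implant abundance tables are sparse samples x taxa matrices of
ppm-normalized read proportions over a mixed community of bacteria, fungi
and viruses. The generator emulates that structure with a zero-inflated
log-normal baseline: each taxon draws a log-mean from a configurable range,
each sample/taxon cell is log-normally distributed around it, and a
Bernoulli mask zeroes a configurable fraction of cells (taxon absent in
that sample). Rows are then ppm-normalized.

Ground-truth signal can be planted on top of the baseline:

* **single markers** — a taxon is up- or down-shifted in every
  peri-implantitis (PI) sample by a multiplicative effect size. Up-shifts
  also force the taxon to be present in PI samples (an enriched organism is
  detected), which is what gives a multiplicative effect realistic power
  under zero inflation.
* **a combination panel** — 2-4 taxa are up-shifted with *partial,
  overlapping penetrance*: each PI sample shifts only ``k`` of the panel's
  ``m`` taxa (``k`` chosen so the per-taxon penetrance matches the
  configured value, and every sample shifts at least ``floor(m *
  penetrance)`` of them). No single taxon separates the groups well, but
  the panel jointly does — the regime in which combination-scoring
  classifiers beat single-marker cutoffs.

Everything is deterministic for a fixed ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import AbundanceTable, CohortLabels, normalize_ppm

DIRECTIONS = ("up", "down")


@dataclass(frozen=True)
class PlantedMarker:
    """A single differentially abundant taxon planted into PI samples."""

    taxon_index: int
    direction: str  # "up" or "down"
    multiplier: float

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"marker direction must be in {DIRECTIONS}")
        if self.multiplier < 1:
            raise ValidationError("effect multiplier must be >= 1")


@dataclass(frozen=True)
class PlantedCombo:
    """A jointly informative panel of taxa, each only partially penetrant."""

    taxon_indices: tuple
    multiplier: float = 12.0
    penetrance: float = 0.9

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxon_indices", tuple(self.taxon_indices))
        if not 2 <= len(self.taxon_indices) <= 4:
            raise ValidationError("combo panel must contain 2-4 taxa")
        if len(set(self.taxon_indices)) != len(self.taxon_indices):
            raise ValidationError("combo taxa must be distinct")
        if self.multiplier < 1:
            raise ValidationError("effect multiplier must be >= 1")
        if not 0.0 < self.penetrance <= 1.0:
            raise ValidationError("penetrance must be in (0, 1]")


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the subgingival-biofilm study cohort: 60 samples
    (40 healthy-implant HI, 20 peri-implantitis PI) over 596 bacterial,
    52 fungal and 586 viral taxa.
    """

    n_hi: int = 40
    n_pi: int = 20
    n_bacteria: int = 596
    n_fungi: int = 52
    n_virus: int = 586
    zero_inflation: float = 0.3
    log_mean_range: tuple = (0.0, 4.0)
    log_sd: float = 0.5
    planted_markers: Sequence[PlantedMarker] = field(default_factory=tuple)
    planted_combo: Optional[PlantedCombo] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hi", "n_pi", "n_bacteria", "n_fungi", "n_virus"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValidationError("zero_inflation must be in [0, 1]")
        if self.log_sd <= 0:
            raise ValidationError("log_sd must be positive")
        lo, hi = self.log_mean_range
        if hi < lo:
            raise ValidationError("log_mean_range must be (low, high) with low <= high")
        self.planted_markers = tuple(
            m if isinstance(m, PlantedMarker) else PlantedMarker(*m)
            for m in self.planted_markers
        )
        up = {m.taxon_index for m in self.planted_markers if m.direction == "up"}
        down = {m.taxon_index for m in self.planted_markers if m.direction == "down"}
        if up & down:
            raise ValidationError(
                f"marker indices planted in both directions: {sorted(up & down)}"
            )
        all_planted = list(up | down)
        if self.planted_combo is not None:
            all_planted += list(self.planted_combo.taxon_indices)
        for idx in all_planted:
            if not 0 <= idx < self.n_taxa:
                raise ValidationError(f"planted taxon index {idx} out of range")

    @property
    def n_taxa(self) -> int:
        return self.n_bacteria + self.n_fungi + self.n_virus

    @property
    def n_samples(self) -> int:
        return self.n_hi + self.n_pi

    @classmethod
    def biofilm_like(cls, **overrides) -> "SyntheticSpec":
        """Cohort shaped like the biofilm dataset (40 HI / 20 PI, 1234 taxa)."""
        return cls(**{"n_hi": 40, "n_pi": 20, **overrides})

    @classmethod
    def saliva_like(cls, **overrides) -> "SyntheticSpec":
        """Cohort shaped like the saliva dataset (20 HI / 20 PI, 1234 taxa)."""
        return cls(**{"n_hi": 20, "n_pi": 20, **overrides})

    def taxon_ids(self) -> list:
        ids = [f"bact_{i:04d}" for i in range(self.n_bacteria)]
        ids += [f"fung_{i:04d}" for i in range(self.n_fungi)]
        ids += [f"vir_{i:04d}" for i in range(self.n_virus)]
        return ids

    def kingdoms(self) -> list:
        return (
            ["bacteria"] * self.n_bacteria
            + ["fungi"] * self.n_fungi
            + ["virus"] * self.n_virus
        )

    def planted_truth(self) -> dict:
        """JSON-serializable manifest of the planted signal (for recovery tests)."""
        ids = self.taxon_ids()
        manifest = {
            "markers": [
                {
                    "taxon_id": ids[m.taxon_index],
                    "taxon_index": m.taxon_index,
                    "direction": m.direction,
                    "multiplier": m.multiplier,
                }
                for m in self.planted_markers
            ],
            "combo": None,
            "seed": self.seed,
        }
        if self.planted_combo is not None:
            manifest["combo"] = {
                "taxon_ids": [ids[i] for i in self.planted_combo.taxon_indices],
                "taxon_indices": list(self.planted_combo.taxon_indices),
                "multiplier": self.planted_combo.multiplier,
                "penetrance": self.planted_combo.penetrance,
            }
        return manifest

    def write_truth_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.planted_truth(), fh, indent=2)


def _penetrance_counts(m: int, penetrance: float, n_pi: int, rng) -> np.ndarray:
    """Number of panel taxa shifted in each PI sample.

    Each count is ``floor(m * penetrance)`` or one more, mixed so the mean
    per-taxon penetrance equals ``penetrance``; overlap across taxa is thus
    structured rather than independent, and every PI sample carries most of
    the panel signal.
    """
    target = m * penetrance
    k_lo = int(np.floor(target))
    frac = target - k_lo
    counts = k_lo + (rng.random(n_pi) < frac).astype(int)
    return np.clip(counts, 1, m)


def generate_cohort(spec: SyntheticSpec) -> tuple[AbundanceTable, CohortLabels]:
    """Draw one labeled cohort from a :class:`SyntheticSpec`.

    Returns a ppm-normalized :class:`AbundanceTable` (rows sum to 1e6) and
    matching :class:`CohortLabels`. HI samples come first, then PI.
    """
    rng = np.random.default_rng(spec.seed)
    n_s, n_t = spec.n_samples, spec.n_taxa

    log_mean = rng.uniform(*spec.log_mean_range, size=n_t)
    base = np.exp(rng.normal(loc=log_mean, scale=spec.log_sd, size=(n_s, n_t)))
    present = rng.random((n_s, n_t)) >= spec.zero_inflation
    values = np.where(present, base, 0.0)

    pi_rows = np.arange(spec.n_hi, n_s)

    for marker in spec.planted_markers:
        j = marker.taxon_index
        if marker.direction == "up":
            # enrichment implies detection: presence forced in PI samples
            values[pi_rows, j] = base[pi_rows, j] * marker.multiplier
        else:
            values[pi_rows, j] = values[pi_rows, j] / marker.multiplier

    combo = spec.planted_combo
    if combo is not None:
        panel = np.asarray(combo.taxon_indices)
        counts = _penetrance_counts(len(panel), combo.penetrance, spec.n_pi, rng)
        for row, k in zip(pi_rows, counts):
            shifted = rng.choice(panel, size=k, replace=False)
            values[row, shifted] = base[row, shifted] * combo.multiplier

    # a fully zeroed sample has no composition; re-seat its largest baseline taxon
    empty = values.sum(axis=1) == 0
    if empty.any():
        for row in np.flatnonzero(empty):
            values[row, np.argmax(base[row])] = base[row].max()

    sample_ids = [f"HI_{i + 1:03d}" for i in range(spec.n_hi)]
    sample_ids += [f"PI_{i + 1:03d}" for i in range(spec.n_pi)]
    table = AbundanceTable(
        pd.DataFrame(values, index=sample_ids, columns=spec.taxon_ids()),
        pd.Series(spec.kingdoms(), index=spec.taxon_ids()),
    )
    labels = CohortLabels(
        pd.Series(["HI"] * spec.n_hi + ["PI"] * spec.n_pi, index=sample_ids)
    )
    return normalize_ppm(table), labels


def spec_to_dict(spec: SyntheticSpec) -> dict:
    """Plain-dict form of a spec (for run manifests)."""
    d = asdict(spec)
    d["planted_markers"] = [asdict(m) for m in spec.planted_markers]
    d["planted_combo"] = (
        None if spec.planted_combo is None else asdict(spec.planted_combo)
    )
    return d


def spec_from_dict(d: dict) -> SyntheticSpec:
    d = dict(d)
    d["planted_markers"] = tuple(
        PlantedMarker(**m) for m in d.get("planted_markers", ())
    )
    combo = d.get("planted_combo")
    if combo is not None:
        combo = dict(combo)
        combo["taxon_indices"] = tuple(combo["taxon_indices"])
        d["planted_combo"] = PlantedCombo(**combo)
    if "log_mean_range" in d:
        d["log_mean_range"] = tuple(d["log_mean_range"])
    return SyntheticSpec(**d)
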