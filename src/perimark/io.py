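"""Core data containers and CSV I/O for abundance tables and cohort labels.

The canonical on-disk layout is samples-as-rows, taxa-as-columns: a header
row of taxon identifiers, a first column named ``sample_id``, and cell
values holding relative abundances in ppm (parts per million of each
sample's total mapped reads, so a normalized row sums to 1e6). An optional
row whose ``sample_id`` is ``kingdom`` annotates each taxon with its
kingdom (``bacteria``, ``fungi``, ``virus`` or ``other``); the annotation
is used only for simulation and reporting, never for classification.

Labels live in a two-column CSV ``sample_id,group`` with group in
``{HI, PI}`` (healthy implant / peri-implantitis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError, FormatError, ValidationError

PPM_TOTAL = 1_000_000.0
KINGDOMS = ("bacteria", "fungi", "virus", "other")
GROUPS = ("HI", "PI")

#: sentinel sample_id for the kingdom annotation row in abundance CSVs
_KINGDOM_ROW = "kingdom"


@dataclass
class AbundanceTable:
    """Samples x taxa matrix of relative abundances (ppm) with kingdom tags.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with one float column per taxon.
        Values must be finite and non-negative.
    kingdom
        Per-taxon kingdom label aligned with ``data.columns``; defaults to
        ``"other"`` for every taxon when not given.
    """

    data: pd.DataFrame
    kingdom: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("data must be a pandas DataFrame")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate taxon ids: {dup}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("abundance values must be numeric")
        self.data = self.data.astype(float)
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite abundance at sample {self.data.index[bad[0]]!r}, "
                f"taxon {self.data.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.data.index[bad[0]]!r}, "
                f"taxon {self.data.columns[bad[1]]!r}"
            )
        if self.kingdom is None:
            self.kingdom = pd.Series("other", index=self.data.columns)
        else:
            self.kingdom = pd.Series(self.kingdom).reindex(self.data.columns)
            self.kingdom = self.kingdom.fillna("other")
            unknown = set(self.kingdom.unique()) - set(KINGDOMS)
            if unknown:
                raise ValidationError(f"unknown kingdom labels: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def values_for(self, taxon_id) -> pd.Series:
        """Abundance vector of one taxon across all samples."""
        if taxon_id not in self.data.columns:
            raise KeyError(f"taxon {taxon_id!r} not in table")
        return self.data[taxon_id]

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)], self.kingdom)

    def is_normalized(self, rtol: float = 1e-9) -> bool:
        sums = self.data.sum(axis=1).to_numpy()
        return bool(np.allclose(sums, PPM_TOTAL, rtol=rtol, atol=0.0))


@dataclass
class CohortLabels:
    """Binary group assignment (HI / PI) per sample."""

    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        if self.labels.index.has_duplicates:
            dup = self.labels.index[self.labels.index.duplicated()].tolist()
            raise FormatError(f"sample listed more than once: {dup}")
        bad = set(self.labels.unique()) - set(GROUPS)
        if bad:
            raise ValidationError(
                f"unknown group token(s) {sorted(map(str, bad))}; expected HI or PI"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.labels.index)

    def group_samples(self, group: str) -> list:
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        return list(self.labels.index[self.labels == group])

    def n_group(self, group: str) -> int:
        return len(self.group_samples(group))

    def align_with(self, table: AbundanceTable) -> pd.Series:
        """Labels reindexed to the table's samples; every sample must be labeled."""
        missing = [s for s in table.sample_ids if s not in self.labels.index]
        if missing:
            raise ValidationError(f"samples without labels: {missing}")
        return self.labels.loc[table.sample_ids]

    def require_both_groups(self) -> None:
        for g in GROUPS:
            if self.n_group(g) == 0:
                raise ValidationError(f"group {g} is empty")


def normalize_ppm(table: AbundanceTable) -> AbundanceTable:
    """Rescale every sample's abundances to sum to 1e6 (ppm).

    Idempotent and ratio-preserving. A sample whose abundances are all zero
    has no defined composition and raises :class:`DegenerateSampleError`.
    """
    totals = table.data.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateSampleError(
            f"sample(s) with all-zero abundance cannot be normalized: "
            f"{list(zero.index)}"
        )
    scaled = table.data.div(totals, axis=0) * PPM_TOTAL
    return AbundanceTable(scaled, table.kingdom)


def read_abundance_csv(path, transpose: bool = False) -> AbundanceTable:
    """Read an abundance CSV into an :class:`AbundanceTable`.

    The expected layout is samples as rows and taxa as columns; pass
    ``transpose=True`` for taxa-as-rows files. A row (or, transposed,
    column) with identifier ``kingdom`` is parsed as the per-taxon kingdom
    annotation rather than as a sample.
    """
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh))[1:]  # pandas would mangle duplicates
    dup = pd.Index(header)
    if dup.has_duplicates:
        names = dup[dup.duplicated()].unique().tolist()
        label = "sample rows" if transpose else "taxon columns"
        raise FormatError(f"{path}: duplicate {label} {names}")
    raw = pd.read_csv(path, index_col=0, dtype=str)
    if transpose:
        raw = raw.T
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        label = "taxon" if transpose else "sample"
        raise FormatError(f"{path}: duplicate {label} ids {dup}")
    kingdom = None
    if _KINGDOM_ROW in raw.index:
        kingdom = raw.loc[_KINGDOM_ROW]
        raw = raw.drop(index=_KINGDOM_ROW)
    if raw.isna().any().any():
        cell = np.argwhere(raw.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing value at sample {raw.index[cell[0]]!r}, "
            f"taxon {raw.columns[cell[1]]!r}"
        )
    raw.index.name = None
    raw.columns.name = None
    try:
        data = raw.astype(float)
    except ValueError as exc:
        for col in raw.columns:
            coerced = pd.to_numeric(raw[col], errors="coerce")
            if coerced.isna().any():
                row = raw.index[coerced.isna()][0]
                raise ValidationError(
                    f"{path}: non-numeric value at sample {row!r}, taxon {col!r}"
                ) from exc
        raise
    return AbundanceTable(data, kingdom)


def write_abundance_csv(table: AbundanceTable, path, include_kingdom: bool = True) -> None:
    """Write an :class:`AbundanceTable` as CSV (samples as rows).

    Uses round-trip float formatting, so ``write -> read`` reproduces the
    table exactly. The kingdom annotation is stored as an extra row whose
    sample id is ``kingdom``.
    """
    out = table.data.copy()
    out.index.name = "sample_id"
    if include_kingdom:
        header = pd.DataFrame(
            [table.kingdom.to_numpy()], index=pd.Index([_KINGDOM_ROW], name="sample_id"),
            columns=out.columns,
        )
        out = pd.concat([header, out.astype(object)])
    out.to_csv(path)


def read_labels_csv(path) -> CohortLabels:
    """Read a two-column ``sample_id,group`` CSV into :class:`CohortLabels`."""
    frame = pd.read_csv(path, dtype=str)
    expected = ["sample_id", "group"]
    if list(frame.columns[:2]) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(frame.columns)}")
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: sample listed more than once: {dup}")
    return CohortLabels(pd.Series(frame["group"].to_numpy(), index=frame["sample_id"].to_numpy()))


def write_labels_csv(labels: CohortLabels, path) -> None:
    frame = pd.DataFrame({"sample_id": labels.sample_ids, "group": labels.labels.to_numpy()})
    frame.to_csv(path, index=False)
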