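"""Count tables, sample metadata, taxonomy — reading, writing, normalisation.

Conventions used throughout the package:

* **Features are rows, samples are columns** (the QIIME orientation).
* Feature and sample IDs are opaque, case-sensitive strings and must be unique.
* Sampling days are calendar-offset integers (e.g. 1, 4, 8, 11, 15, 19), not
  indices; ordering is numeric.
* TSV is the canonical interchange format; BIOM 2.1 is supported for
  interoperability with QIIME/DADA2 exports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Compartment",
    "CountTable",
    "RelAbundanceTable",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "total_sum_scaling",
    "filter_min_abundance",
    "TAXONOMY_RANKS",
]

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class Compartment(str, Enum):
    """Sampled habitat of a sample: snow layers, soil, or a negative control."""

    SURFACE_SNOW = "surface_snow"
    BULK_SNOW = "bulk_snow"
    SOIL = "soil"
    NEGATIVE_CONTROL = "negative_control"


SNOW_COMPARTMENTS = frozenset({Compartment.SURFACE_SNOW, Compartment.BULK_SNOW})


class TableValidationError(ValueError):
    """Raised when a table violates its structural invariants."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate {what} IDs: {dups[:5]}")


@dataclass(frozen=True)
class CountTable:
    """Integer feature x sample count matrix with string IDs.

    Invariants enforced at construction: non-negative integer counts, unique
    feature and sample IDs, at least one feature and one sample (use
    ``allow_empty_features=True`` internally for filtered-to-empty tables,
    which downstream operations must tolerate).
    """

    counts: np.ndarray
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise TableValidationError("counts must be a 2-D matrix")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise TableValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise TableValidationError("counts must be non-negative")
        if counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise TableValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(self.sample_ids) < 1:
            raise TableValidationError("need at least one sample")
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        """Build from a DataFrame with feature IDs as index, sample IDs as columns."""
        return cls(
            counts=frame.to_numpy(),
            feature_ids=tuple(str(i) for i in frame.index),
            sample_ids=tuple(str(c) for c in frame.columns),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.copy(), index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    def select_features(self, keep: Iterable[str]) -> "CountTable":
        """Subset to the given features, preserving original row order."""
        keep = set(keep)
        idx = [i for i, f in enumerate(self.feature_ids) if f in keep]
        return CountTable(
            counts=self.counts[idx, :],
            feature_ids=tuple(self.feature_ids[i] for i in idx),
            sample_ids=self.sample_ids,
        )

    def select_samples(self, keep: Iterable[str]) -> "CountTable":
        keep = set(keep)
        idx = [j for j, s in enumerate(self.sample_ids) if s in keep]
        return CountTable(
            counts=self.counts[:, idx],
            feature_ids=self.feature_ids,
            sample_ids=tuple(self.sample_ids[j] for j in idx),
        )


@dataclass(frozen=True)
class RelAbundanceTable:
    """Relative-abundance (total-sum-scaled) feature x sample matrix.

    Each column sums to 1, except columns that were all-zero in the source
    table, which stay all-zero.
    """

    fractions: np.ndarray
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        frac = np.asarray(self.fractions, dtype=float)
        if frac.size and (frac.min() < 0 or frac.max() > 1 + 1e-9):
            raise TableValidationError("fractions must lie in [0, 1]")
        colsums = frac.sum(axis=0) if frac.size else np.zeros(len(self.sample_ids))
        bad = ~(np.isclose(colsums, 1.0, atol=1e-9) | np.isclose(colsums, 0.0))
        if bad.any():
            raise TableValidationError("column sums must be 0 or 1")
        object.__setattr__(self, "fractions", frac)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fractions.copy(), index=list(self.feature_ids), columns=list(self.sample_ids)
        )


# ---------------------------------------------------------------------------
# I/O


def read_count_table(path: str | Path, format: str = "tsv") -> CountTable:
    """Read a feature x sample count table.

    TSV dialect: first column holds feature IDs, header row holds sample IDs,
    cells are tab-separated integers. BIOM files are read through the ``biom``
    package (BIOM 2.1 HDF5 or 1.0 JSON).
    """
    path = Path(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        numeric = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
        for col in frame.columns:
            converted = pd.to_numeric(frame[col], errors="coerce")
            bad = converted.isna() & frame[col].notna()
            if bad.any():
                row = frame.index[bad.argmax()]
                raise TableValidationError(
                    f"malformed numeric cell at feature {row!r}, sample {col!r}"
                )
            numeric[col] = converted
        if numeric.isna().any().any():
            raise TableValidationError("missing cells in count table")
        return CountTable.from_frame(numeric)
    if format == "biom":
        import biom

        bt = biom.load_table(str(path))
        return CountTable(
            counts=np.asarray(bt.matrix_data.todense()),
            feature_ids=tuple(bt.ids("observation")),
            sample_ids=tuple(bt.ids("sample")),
        )
    raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'biom')")


def write_count_table(table: CountTable, path: str | Path, format: str = "tsv") -> None:
    """Write a count table as TSV (``feature_id`` header) or BIOM 2.1 HDF5."""
    path = Path(path)
    if format == "tsv":
        frame = table.to_frame()
        frame.index.name = "feature_id"
        frame.to_csv(path, sep="\t")
        return
    if format == "biom":
        import biom

        bt = biom.Table(
            table.counts, list(table.feature_ids), list(table.sample_ids)
        )
        with biom.util.biom_open(str(path), "w") as fh:
            bt.to_hdf5(fh, "meltcol")
        return
    raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'biom')")


_META_COLUMNS = ("sample_id", "compartment", "day", "is_control")
_TRUE_STRINGS = {"true", "1", "yes", "t"}
_FALSE_STRINGS = {"false", "0", "no", "f"}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise TableValidationError(f"cannot parse boolean value {value!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata (CSV or TSV, sniffed from the header line).

    Required columns: ``sample_id``, ``compartment``, ``day``, ``is_control``.
    Returns a DataFrame indexed by ``sample_id`` with columns ``compartment``
    (str), ``day`` (nullable int) and ``is_control`` (bool), validated by
    :func:`validate_metadata`.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _META_COLUMNS if c not in raw.columns]
    if missing:
        raise TableValidationError(f"metadata missing required columns: {missing}")
    meta = pd.DataFrame(
        {
            "compartment": raw["compartment"].str.strip().to_numpy(),
            "day": pd.to_numeric(raw["day"], errors="coerce").astype("Int64").to_numpy(),
            "is_control": [_parse_bool(v) for v in raw["is_control"]],
        },
        index=pd.Index(raw["sample_id"].str.strip().to_numpy(), name="sample_id"),
    )
    validate_metadata(meta)
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def validate_metadata(meta: pd.DataFrame) -> None:
    """Enforce metadata invariants.

    ``is_control`` must be true iff ``compartment == negative_control`` and
    every non-control sample needs a day.
    """
    allowed = {c.value for c in Compartment}
    bad = sorted(set(meta["compartment"]) - allowed)
    if bad:
        raise TableValidationError(
            f"unknown compartment value(s) {bad}; allowed: {sorted(allowed)}"
        )
    _check_unique(list(meta.index), "sample")
    is_neg = meta["compartment"] == Compartment.NEGATIVE_CONTROL.value
    if not (meta["is_control"].astype(bool) == is_neg).all():
        raise TableValidationError(
            "is_control must be true exactly for negative_control samples"
        )
    noncontrol_missing_day = (~meta["is_control"].astype(bool)) & meta["day"].isna()
    if noncontrol_missing_day.any():
        who = meta.index[noncontrol_missing_day].tolist()
        raise TableValidationError(f"non-control samples lack a day: {who[:5]}")


def check_paired(table: CountTable, meta: pd.DataFrame) -> None:
    """Require that metadata covers every sample in the table."""
    missing = set(table.sample_ids) - set(meta.index)
    if missing:
        raise TableValidationError(
            f"samples missing from metadata: {sorted(missing)[:5]}"
        )


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy table: ``feature_id`` plus rank columns (domain..genus).

    Missing ranks are allowed and stored as NA. Extra rank columns are
    preserved; rank order follows :data:`TAXONOMY_RANKS` where present.
    """
    tax = pd.read_csv(path, sep="\t", dtype=str).set_index("feature_id")
    ordered = [r for r in TAXONOMY_RANKS if r in tax.columns]
    others = [c for c in tax.columns if c not in ordered]
    tax = tax[ordered + others]
    tax = tax.replace({"": pd.NA})
    _check_unique(list(tax.index), "feature")
    return tax


# ---------------------------------------------------------------------------
# Normalisation / filtering


def total_sum_scaling(table: CountTable) -> RelAbundanceTable:
    """Normalise each sample (column) by its library size.

    Accounts for uneven sequencing depth across samples. All-zero columns are
    left at zero and reported with a warning rather than an error, since an
    empty sample can legitimately arise after contaminant removal.
    """
    counts = table.counts.astype(float)
    colsums = counts.sum(axis=0)
    zero_cols = colsums == 0
    if zero_cols.any():
        empty = [table.sample_ids[j] for j in np.flatnonzero(zero_cols)]
        warnings.warn(f"all-zero sample(s) left unnormalised: {empty}", stacklevel=2)
    safe = np.where(zero_cols, 1.0, colsums)
    return RelAbundanceTable(
        fractions=counts / safe,
        feature_ids=table.feature_ids,
        sample_ids=table.sample_ids,
    )


def filter_min_abundance(table: CountTable, min_count: int) -> CountTable:
    """Drop features whose total count across all samples is below ``min_count``.

    ``min_count=0`` is the identity. The operation is idempotent and preserves
    the order of surviving features. A table filtered to zero features is
    valid; downstream operations must tolerate it.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    totals = table.counts.sum(axis=1)
    keep = totals >= min_count
    return CountTable(
        counts=table.counts[keep, :],
        feature_ids=tuple(f for f, k in zip(table.feature_ids, keep) if k),
        sample_ids=table.sample_ids,
    )
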