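"""Chemical x assay potency matrices: container, file dialect, filters, profiling.

The central object is :class:`ChemAssayMatrix`, a labelled 2-D grid of
negative-log-transformed AC50 values (unitless; larger = more potent,
exactly 0 = tested inactive). Missing cells — chemical/assay pairs never
tested — are represented as NaN and are strictly distinct from present
zeros throughout the package: a ``0`` in a cell means tested-inactive,
never untested.

File dialect: comma-delimited text, header row of assay IDs, first column
of chemical IDs, ``NA`` (or an empty cell) as the missing token, numbers
written at full precision. A plain-text chemical list is one identifier
per line.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChemAssayMatrix",
    "MissingnessProfile",
    "MatrixFormatError",
    "load_matrix",
    "write_matrix",
    "load_chemical_list",
    "subset_chemicals",
    "filter_full_missing_assays",
    "missingness_profile",
]


class MatrixFormatError(ValueError):
    """Raised when a matrix file violates the dialect (ragged rows, duplicate IDs...)."""


@dataclass
class ChemAssayMatrix:
    """A chemical x assay matrix of non-negative potencies with explicit missingness.

    Parameters
    ----------
    chemical_ids : list of str
        Row labels, unique.
    assay_ids : list of str
        Column labels, unique.
    values : ndarray of float, shape (n_chemicals, n_assays)
        Potency values; NaN marks a missing (untested) cell.
    source_labels : list of str, optional
        Per-assay source (technology platform) labels; drives the
        baseline slice structure when present.
    """

    chemical_ids: list[str]
    assay_ids: list[str]
    values: np.ndarray
    source_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.chemical_ids = [str(c) for c in self.chemical_ids]
        self.assay_ids = [str(a) for a in self.assay_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.chemical_ids),
            len(self.assay_ids),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.chemical_ids)} chemicals x {len(self.assay_ids)} assays"
            )
        if len(set(self.chemical_ids)) != len(self.chemical_ids):
            raise MatrixFormatError("duplicate chemical identifiers")
        if len(set(self.assay_ids)) != len(self.assay_ids):
            raise MatrixFormatError("duplicate assay identifiers")
        if self.source_labels is not None and len(self.source_labels) != len(self.assay_ids):
            raise ValueError("source_labels length does not match assay count")

    @property
    def n_chemicals(self) -> int:
        return len(self.chemical_ids)

    @property
    def n_assays(self) -> int:
        return len(self.assay_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where a cell is missing."""
        return np.isnan(self.values)

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def copy(self) -> "ChemAssayMatrix":
        return ChemAssayMatrix(
            list(self.chemical_ids),
            list(self.assay_ids),
            self.values.copy(),
            list(self.source_labels) if self.source_labels is not None else None,
        )

    def with_values(self, values: np.ndarray) -> "ChemAssayMatrix":
        """Same labels, new value grid."""
        return ChemAssayMatrix(
            list(self.chemical_ids),
            list(self.assay_ids),
            np.asarray(values, dtype=float),
            list(self.source_labels) if self.source_labels is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.chemical_ids, columns=self.assay_ids)

    def equals(self, other: "ChemAssayMatrix") -> bool:
        """Label equality plus value equality treating NaN == NaN."""
        return (
            self.chemical_ids == other.chemical_ids
            and self.assay_ids == other.assay_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass
class MissingnessProfile:
    """Fractions of missing cells per chemical, per assay, and overall."""

    per_chemical_fraction: np.ndarray
    per_assay_fraction: np.ndarray
    overall_fraction: float

    def chemical_range(self) -> tuple[float, float]:
        return float(self.per_chemical_fraction.min()), float(self.per_chemical_fraction.max())

    def assay_range(self) -> tuple[float, float]:
        return float(self.per_assay_fraction.min()), float(self.per_assay_fraction.max())


def _prescan(path: Path, delimiter: str) -> None:
    """Reject ragged rows and duplicate IDs before pandas mangles them."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        header = next(reader, None)
        if header is None:
            raise MatrixFormatError(f"{path}: empty file")
        width = len(header)
        assay_ids = header[1:]
        if len(set(assay_ids)) != len(assay_ids):
            raise MatrixFormatError(f"{path}: duplicate assay identifiers in header")
        chem_ids = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != width:
                raise MatrixFormatError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(row)} fields, expected {width})"
                )
            chem_ids.append(row[0])
        if len(set(chem_ids)) != len(chem_ids):
            raise MatrixFormatError(f"{path}: duplicate chemical identifiers")


def load_matrix(
    path: str | Path,
    missing_token: str = "NA",
    delimiter: str = ",",
    allow_negative: bool = False,
) -> ChemAssayMatrix:
    """Read a chemical x assay matrix from delimited text.

    First row holds assay IDs, first column chemical IDs; cells are
    decimal numbers or the missing token (empty cells also count as
    missing). Negative present values are rejected unless
    ``allow_negative`` is set (imputed matrices written by this package
    may contain small negative predictions).
    """
    path = Path(path)
    _prescan(path, delimiter)
    df = pd.read_csv(
        path,
        sep=delimiter,
        index_col=0,
        keep_default_na=False,
        na_values=[missing_token, ""],
        float_precision="round_trip",
    )
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: non-numeric cell: {exc}") from exc
    if not allow_negative:
        with np.errstate(invalid="ignore"):
            if np.any(values < 0):
                i, j = np.argwhere(values < 0)[0]
                raise ValueError(
                    f"{path}: negative value {values[i, j]} at chemical "
                    f"{df.index[i]!r}, assay {df.columns[j]!r}; potencies must be >= 0"
                )
    return ChemAssayMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_matrix(
    matrix: ChemAssayMatrix,
    path: str | Path,
    missing_token: str = "NA",
    delimiter: str = ",",
) -> None:
    """Write the matrix in the dialect :func:`load_matrix` reads (UTF-8, full precision)."""
    df = matrix.to_frame()
    # %.17g round-trips IEEE double exactly
    df.to_csv(path, sep=delimiter, na_rep=missing_token, encoding="utf-8",
              float_format="%.17g")


def load_chemical_list(path: str | Path) -> list[str]:
    """Read a chemical list: one identifier per line, blanks ignored."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def subset_chemicals(matrix: ChemAssayMatrix, keep_list: list[str]) -> ChemAssayMatrix:
    """Restrict rows to chemicals in ``keep_list``, preserving original row order.

    Mirrors the intersection of a screening matrix with an external
    priority list. Raises if the intersection is empty.
    """
    keep = set(keep_list)
    rows = [i for i, c in enumerate(matrix.chemical_ids) if c in keep]
    if not rows:
        raise ValueError("no chemicals shared between matrix and keep list")
    return ChemAssayMatrix(
        [matrix.chemical_ids[i] for i in rows],
        list(matrix.assay_ids),
        matrix.values[rows, :],
        list(matrix.source_labels) if matrix.source_labels is not None else None,
    )


def filter_full_missing_assays(
    matrix: ChemAssayMatrix,
) -> tuple[ChemAssayMatrix, list[str]]:
    """Drop assays with no observed value (100% missing), preserving column order.

    Returns the filtered matrix and the list of removed assay IDs.
    Raises if every assay would be removed.
    """
    keep = ~np.all(np.isnan(matrix.values), axis=0)
    removed = [a for a, k in zip(matrix.assay_ids, keep) if not k]
    if not keep.any():
        raise ValueError("all assays are 100% missing; nothing to analyze")
    filtered = ChemAssayMatrix(
        list(matrix.chemical_ids),
        [a for a, k in zip(matrix.assay_ids, keep) if k],
        matrix.values[:, keep],
        [s for s, k in zip(matrix.source_labels, keep) if k]
        if matrix.source_labels is not None
        else None,
    )
    return filtered, removed


def missingness_profile(matrix: ChemAssayMatrix) -> MissingnessProfile:
    """Fraction of missing cells per chemical (row), per assay (column), and overall."""
    miss = np.isnan(matrix.values)
    return MissingnessProfile(
        per_chemical_fraction=miss.mean(axis=1),
        per_assay_fraction=miss.mean(axis=0),
        overall_fraction=float(miss.mean()),
    )
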