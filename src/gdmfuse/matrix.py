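"""Core labeled data containers and distance-matrix I/O.

The central object is :class:`LabeledDistanceMatrix`, a symmetric
nonnegative square matrix of genetic distances keyed by unique population
labels, with ``NaN`` encoding missing cells.  Allele-frequency tables
(populations x loci, values in [0, 1]) are the upstream input from which
Nei distances are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlleleFrequencyTable",
    "LabeledDistanceMatrix",
    "FilterThresholds",
    "MatrixFormatError",
    "read_distance_matrix",
    "write_distance_matrix",
]


class MatrixFormatError(ValueError):
    """Raised when an on-disk matrix violates the format contract."""


def _check_unique(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        seen, dups = set(), []
        for x in labels:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")
    return labels


@dataclass
class AlleleFrequencyTable:
    """Reference-allele frequencies per (population, locus).

    Parameters
    ----------
    population_ids : sequence of str
        Unique population (sample) labels, one per row.
    locus_ids : sequence of str
        Unique locus identifiers, one per column.
    freq : ndarray of shape (n_populations, n_loci)
        Reference-allele frequency in ``[0, 1]``; ``NaN`` marks missing.
    """

    population_ids: list[str]
    locus_ids: list[str]
    freq: np.ndarray

    def __post_init__(self) -> None:
        self.population_ids = _check_unique(self.population_ids, "population ids")
        self.locus_ids = _check_unique(self.locus_ids, "locus ids")
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.population_ids), len(self.locus_ids)):
            raise ValueError(
                f"freq shape {self.freq.shape} does not match "
                f"{len(self.population_ids)} populations x {len(self.locus_ids)} loci"
            )
        present = self.freq[~np.isnan(self.freq)]
        if present.size and (present.min() < 0 or present.max() > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_populations(self) -> int:
        return len(self.population_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freq, index=self.population_ids, columns=self.locus_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleFrequencyTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class FilterThresholds:
    """Site/sample retention thresholds for pooled-sequencing genotyping.

    A site-sample call is kept only when its read depth exceeds
    ``depth_min`` (strict).  Loci whose missing fraction reaches
    ``locus_missing_max`` are dropped, then samples whose missing fraction
    reaches ``sample_missing_max``.
    """

    depth_min: int = 5
    locus_missing_max: float = 0.05
    sample_missing_max: float = 0.20

    def __post_init__(self) -> None:
        if self.depth_min < 0:
            raise ValueError("depth_min must be >= 0")
        for name in ("locus_missing_max", "sample_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class LabeledDistanceMatrix:
    """Symmetric nonnegative distance matrix with unique row/column labels.

    ``NaN`` entries encode missing distances.  The diagonal must be zero
    and present; off-diagonal entries are validated symmetric where both
    halves are present.
    """

    labels: list[str]
    d: np.ndarray
    _validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.labels = _check_unique(self.labels, "labels")
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} labels")
        if self._validate:
            self.validate()

    def validate(self, sym_tol: float = 1e-9) -> None:
        diag = np.diag(self.d)
        if np.any(np.isnan(diag)) or np.any(np.abs(diag) > sym_tol):
            raise ValueError("diagonal must be present and zero")
        both = ~np.isnan(self.d) & ~np.isnan(self.d.T)
        if np.any(np.abs((self.d - self.d.T)[both]) > sym_tol):
            i, j = np.unravel_index(
                np.nanargmax(np.where(both, np.abs(self.d - self.d.T), 0.0)), self.d.shape
            )
            raise ValueError(
                f"asymmetry beyond tolerance at ({self.labels[i]}, {self.labels[j]}): "
                f"{self.d[i, j]} vs {self.d[j, i]}"
            )
        off = self.d[~np.eye(len(self.labels), dtype=bool)]
        off = off[~np.isnan(off)]
        if off.size and off.min() < 0:
            raise ValueError("negative distances are not allowed")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def is_complete(self) -> bool:
        return not np.any(np.isnan(self.d))

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(label) from None

    def submatrix(self, labels: Sequence[str]) -> "LabeledDistanceMatrix":
        idx = [self.index_of(x) for x in labels]
        return LabeledDistanceMatrix(list(labels), self.d[np.ix_(idx, idx)])

    def symmetrized(self) -> "LabeledDistanceMatrix":
        """Average the two triangles (NaN-aware) and zero the diagonal."""
        with np.errstate(invalid="ignore"):
            d = np.where(
                np.isnan(self.d), self.d.T,
                np.where(np.isnan(self.d.T), self.d, 0.5 * (self.d + self.d.T)),
            )
        np.fill_diagonal(d, 0.0)
        return LabeledDistanceMatrix(list(self.labels), d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledDistanceMatrix):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(
            self.d, other.d, equal_nan=True
        )


# ---------------------------------------------------------------------------
# I/O: labeled CSV square, PHYLIP square, PHYLIP lower-triangle
# ---------------------------------------------------------------------------

_FORMATS = ("csv-square", "phylip-square", "phylip-lower")


def _validate_read(labels: list[str], d: np.ndarray, sym_tol: float = 1e-9
                   ) -> LabeledDistanceMatrix:
    n = len(labels)
    if d.shape != (n, n):
        raise MatrixFormatError(f"matrix is not square: shape {d.shape} for {n} labels")
    m = LabeledDistanceMatrix(labels, d, _validate=False)
    m.validate(sym_tol=sym_tol)
    # symmetrise away round-off introduced by decimal serialisation
    return m.symmetrized()


def read_distance_matrix(path: str | Path, format: str = "csv-square"
                         ) -> LabeledDistanceMatrix:
    """Read a labeled distance matrix from CSV or PHYLIP.

    CSV carries labels in the first row and column with ``NA`` for
    missing; PHYLIP formats follow the standard count-header layout
    (lower-triangle variants are mirrored to a full matrix).
    """
    path = Path(path)
    if format == "csv-square":
        df = pd.read_csv(path, index_col=0, na_values=["NA"],
                         keep_default_na=True, float_precision="round_trip")
        labels = [str(x) for x in df.index]
        col_labels = [str(x) for x in df.columns]
        if labels != col_labels:
            raise MatrixFormatError(
                f"row labels differ from column labels in {path.name}"
            )
        return _validate_read(labels, df.to_numpy(dtype=float))
    if format in ("phylip-square", "phylip-lower"):
        lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
        try:
            n = int(lines[0].split()[0])
        except (IndexError, ValueError):
            raise MatrixFormatError(f"missing taxon-count header in {path.name}") from None
        labels, rows = [], []
        for ln in lines[1 : n + 1]:
            parts = ln.split()
            labels.append(parts[0])
            rows.append([np.nan if p == "NA" else float(p) for p in parts[1:]])
        if len(labels) != n:
            raise MatrixFormatError(f"expected {n} taxa, found {len(labels)}")
        if format == "phylip-square":
            d = np.asarray(rows, dtype=float)
        else:
            d = np.zeros((n, n))
            for i, row in enumerate(rows):
                if len(row) != i:
                    raise MatrixFormatError(
                        f"lower-triangle row {labels[i]} has {len(row)} entries, expected {i}"
                    )
                d[i, :i] = row
                d[:i, i] = row
        return _validate_read(labels, d)
    raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")


def write_distance_matrix(m: LabeledDistanceMatrix, path: str | Path,
                          format: str = "csv-square") -> None:
    """Write a labeled distance matrix; inverse of :func:`read_distance_matrix`."""
    path = Path(path)
    if format == "csv-square":
        m.to_frame().to_csv(path, na_rep="NA", float_format="%.17g")
        return
    if format in ("phylip-square", "phylip-lower"):
        with open(path, "w") as fh:
            fh.write(f"{m.n}\n")
            for i, lab in enumerate(m.labels):
                row = m.d[i, :i] if format == "phylip-lower" else m.d[i]
                vals = " ".join("NA" if np.isnan(v) else f"{v:.17g}" for v in row)
                fh.write(f"{lab} {vals}".rstrip() + "\n")
        return
    raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
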