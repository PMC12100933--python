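"""Merging a calibrated matrix pair into one union matrix.

After calibration, the two studies agree (up to noise) on their shared
populations, so the union matrix averages shared-pair distances and
copies within-study distances.  Pairs of populations unique to different
studies were never co-measured: those cells are *structurally missing* —
whole cross-blocks of NAs rather than scattered gaps — and are the target
of the chained imputation in :mod:`gdmfuse.impute`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import LabeledDistanceMatrix

__all__ = ["Provenance", "MergedMatrix", "merge_matrices", "missing_summary"]


class Provenance:
    """Per-cell origin tags of a merged matrix."""

    FROM_A = "from_A"
    FROM_B = "from_B"
    AVERAGED = "averaged"
    STRUCTURAL_MISSING = "structural_missing"
    IMPUTED = "imputed"
    DIAGONAL = "diagonal"


@dataclass
class MergedMatrix:
    """Union-labeled distance matrix with per-cell provenance.

    ``values`` is n x n with NaN at structurally missing cells;
    ``provenance`` is a parallel matrix of :class:`Provenance` tags;
    ``in_A`` / ``in_B`` flag each label's study membership.
    """

    labels: list[str]
    values: np.ndarray
    provenance: np.ndarray
    in_A: np.ndarray
    in_B: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def a_side_labels(self) -> list[str]:
        return [l for l, f in zip(self.labels, self.in_A) if f]

    @property
    def b_side_labels(self) -> list[str]:
        return [l for l, f in zip(self.labels, self.in_B) if f]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def as_distance_matrix(self) -> LabeledDistanceMatrix:
        return LabeledDistanceMatrix(list(self.labels), self.values.copy())

    def copy(self) -> "MergedMatrix":
        return MergedMatrix(
            list(self.labels), self.values.copy(), self.provenance.copy(),
            self.in_A.copy(), self.in_B.copy(),
        )

    def write(self, path: str | Path, provenance_path: str | Path | None = None
              ) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, na_rep="NA", float_format="%.17g"
        )
        if provenance_path is not None:
            pd.DataFrame(
                self.provenance, index=self.labels, columns=self.labels
            ).to_csv(provenance_path)


def merge_matrices(A: LabeledDistanceMatrix, Bp: LabeledDistanceMatrix
                   ) -> MergedMatrix:
    """Merge two complete calibrated matrices into a union matrix.

    Shared-pair cells are the average of the two studies; pairs measured
    within a single study are copied; pairs of populations unique to
    different studies become structurally missing.  Label order: A's
    labels, then B's unique labels.
    """
    if not A.is_complete or not Bp.is_complete:
        raise ValueError("both matrices must be complete before merging")
    setA, setB = set(A.labels), set(Bp.labels)
    shared = setA & setB
    if not shared:
        warnings.warn(
            "no shared populations: merged matrix is a block-diagonal union",
            RuntimeWarning, stacklevel=2,
        )
    labels = list(A.labels) + [l for l in Bp.labels if l not in setA]
    n = len(labels)
    in_A = np.array([l in setA for l in labels])
    in_B = np.array([l in setB for l in labels])
    ia = {l: k for k, l in enumerate(A.labels)}
    ib = {l: k for k, l in enumerate(Bp.labels)}
    values = np.full((n, n), np.nan)
    prov = np.full((n, n), Provenance.STRUCTURAL_MISSING, dtype=object)
    for i, li in enumerate(labels):
        for j, lj in enumerate(labels):
            if i == j:
                values[i, j] = 0.0
                prov[i, j] = Provenance.DIAGONAL
                continue
            a_has = in_A[i] and in_A[j]
            b_has = in_B[i] and in_B[j]
            if a_has and b_has:
                values[i, j] = 0.5 * (A.d[ia[li], ia[lj]] + Bp.d[ib[li], ib[lj]])
                prov[i, j] = Provenance.AVERAGED
            elif a_has:
                values[i, j] = A.d[ia[li], ia[lj]]
                prov[i, j] = Provenance.FROM_A
            elif b_has:
                values[i, j] = Bp.d[ib[li], ib[lj]]
                prov[i, j] = Provenance.FROM_B
    return MergedMatrix(labels, values, prov, in_A, in_B)


def missing_summary(M: MergedMatrix) -> dict:
    """Count of missing cells and their fraction over all n^2 cells."""
    count = int(np.isnan(M.values).sum())
    return {"count": count, "fraction": count / M.n**2, "n": M.n}
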