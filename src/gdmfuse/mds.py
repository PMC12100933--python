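"""Classical multidimensional scaling (principal coordinates) of labeled GDMs.

A distance matrix ``D`` is embedded into Euclidean coordinates by
eigendecomposition of the double-centred Gram matrix

    G = -1/2 * H (D ∘ D) H,    H = I - (1/n) 11'

where ``∘`` is the elementwise (Hadamard) square.  Retained axes are those
with eigenvalue above a relative tolerance times the largest eigenvalue;
coordinates are eigenvectors scaled by the square root of their
eigenvalue.  Cumulative explained variance is reported under both the
positive-eigenvalue and absolute-eigenvalue denominator conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator

from .matrix import LabeledDistanceMatrix

__all__ = [
    "MdsConfiguration",
    "ClassicalMDS",
    "classical_mds",
    "shared_dimension",
    "distances_from_config",
]


@dataclass
class MdsConfiguration:
    """A labeled point configuration with its MDS eigen-spectrum.

    ``coords`` is n x m with columns ordered by nonincreasing eigenvalue;
    ``eigenvalues`` are the positive retained eigenvalues.  Explained
    variance fractions are provided with the positive-sum denominator
    (``cumulative_explained``) and with the absolute-value-sum denominator
    (``cumulative_explained_abs``).
    """

    labels: list[str]
    coords: np.ndarray
    eigenvalues: np.ndarray
    cumulative_explained: np.ndarray
    cumulative_explained_abs: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.coords.shape[0] != len(self.labels):
            raise ValueError("one coordinate row per label required")

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())

    def truncated(self, zeta: int) -> "MdsConfiguration":
        """First ``zeta`` axes; zero-padded if fewer are available."""
        m = self.coords.shape[1]
        if zeta <= m:
            coords = self.coords[:, :zeta]
            eig = self.eigenvalues[:zeta]
        else:
            coords = np.hstack(
                [self.coords, np.zeros((self.coords.shape[0], zeta - m))]
            )
            eig = np.concatenate([self.eigenvalues, np.zeros(zeta - m)])
        k = min(zeta, len(self.cumulative_explained))
        return MdsConfiguration(
            list(self.labels), coords, eig,
            self.cumulative_explained[:k], self.cumulative_explained_abs[:k],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{k + 1}" for k in range(self.n_axes)]
        return pd.DataFrame(self.coords, index=self.labels, columns=cols)


class ClassicalMDS(BaseEstimator):
    """Torgerson classical scaling of a labeled distance matrix.

    Parameters
    ----------
    eig_rel_tol : float, default 1e-9
        Axes with eigenvalue below ``eig_rel_tol * max(eigenvalue)`` (or
        nonpositive) are dropped.

    Attributes
    ----------
    embedding_ : MdsConfiguration
        Labels, coordinates and eigen-spectrum of the fitted projection.
    n_axes_ : int
        Number of retained (positive) axes.
    eigenvalues_ : ndarray
        All eigenvalues of the centred Gram matrix, nonincreasing.
    """

    def __init__(self, eig_rel_tol: float = 1e-9):
        self.eig_rel_tol = eig_rel_tol

    def fit(self, D: LabeledDistanceMatrix) -> "ClassicalMDS":
        if not isinstance(D, LabeledDistanceMatrix):
            raise TypeError("ClassicalMDS requires a LabeledDistanceMatrix")
        if not D.is_complete:
            raise ValueError("matrix has missing entries; impute first")
        n = D.n
        if n < 2:
            raise ValueError("need at least 2 populations to embed")
        sq = D.d ** 2
        H = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * H @ sq @ H
        G = 0.5 * (G + G.T)
        evals, evecs = eigh(G)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        if evals.max() <= 0 or evals.max() <= self.eig_rel_tol * abs(evals).max():
            raise ValueError("degenerate input: no positive eigenvalue (all points coincide?)")
        keep = evals > self.eig_rel_tol * evals.max()
        lam = evals[keep]
        coords = evecs[:, keep] * np.sqrt(lam)
        self.eigenvalues_ = evals
        self.n_axes_ = int(keep.sum())
        pos_sum = evals[evals > 0].sum()
        abs_sum = np.abs(evals).sum()
        self.embedding_ = MdsConfiguration(
            list(D.labels), coords, lam,
            np.cumsum(lam) / pos_sum, np.cumsum(lam) / abs_sum,
        )
        return self

    def fit_transform(self, D: LabeledDistanceMatrix) -> np.ndarray:
        return self.fit(D).embedding_.coords


def classical_mds(D: LabeledDistanceMatrix, eig_rel_tol: float = 1e-9
                  ) -> MdsConfiguration:
    """Embed a complete distance matrix; see :class:`ClassicalMDS`."""
    return ClassicalMDS(eig_rel_tol=eig_rel_tol).fit(D).embedding_


def shared_dimension(cfgA: MdsConfiguration, cfgB: MdsConfiguration) -> int:
    """Largest dimensionality supported by both configurations.

    The smallest of the two retained-axis counts: every axis beyond it has
    a nonpositive eigenvalue in at least one study.
    """
    if cfgA.n_axes == 0 or cfgB.n_axes == 0:
        raise ValueError("empty configuration")
    return min(cfgA.n_axes, cfgB.n_axes)


def distances_from_config(cfg: MdsConfiguration) -> LabeledDistanceMatrix:
    """Back-map a configuration to distance space via pairwise Euclidean norms."""
    d = squareform(pdist(cfg.coords))
    return LabeledDistanceMatrix(list(cfg.labels), d)
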