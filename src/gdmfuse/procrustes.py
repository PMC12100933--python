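"""Procrustes calibration of one MDS configuration onto another.

Two studies genotyped on incompatible platforms yield distance matrices
whose Euclidean embeddings differ by an unknown similarity transform.
Using the populations shared between studies as anchors, the calibration

    Y' = s Y R + tau

is estimated over the first ``zeta`` axes: ``s`` is the ratio of Frobenius
norms of the centred shared configurations, ``R`` the orthogonal matrix
(reflections permitted) minimising the Frobenius discrepancy of the
centred anchors, obtained from the SVD of their cross-covariance, and
``tau`` re-centres the scaled, rotated cloud.  Alignment quality is
summarised in distance space by the mean signed bias over shared pairs and
the sum of squared differences (SSD).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .matrix import LabeledDistanceMatrix
from .mds import MdsConfiguration

__all__ = [
    "ProcrustesTransform",
    "ProcrustesAlignment",
    "fit_procrustes",
    "apply_procrustes",
    "alignment_diagnostics",
]


@dataclass
class ProcrustesTransform:
    """A fitted similarity transform with its anchor diagnostics."""

    scale_s: float
    rotation_R: np.ndarray
    translation_tau: np.ndarray
    shared_labels: list[str]
    ssd_before: float
    ssd_after: float
    bias_mean_before: float
    bias_mean_after: float

    @property
    def zeta(self) -> int:
        return self.rotation_R.shape[0]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"scale {self.scale_s:.17g}\n")
            fh.write("shared " + " ".join(self.shared_labels) + "\n")
            fh.write("tau " + " ".join(f"{v:.17g}" for v in self.translation_tau) + "\n")
            for row in self.rotation_R:
                fh.write("R " + " ".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ProcrustesTransform":
        scale, shared, tau, rows = 1.0, [], [], []
        for ln in Path(path).read_text().splitlines():
            key, *rest = ln.split()
            if key == "scale":
                scale = float(rest[0])
            elif key == "shared":
                shared = rest
            elif key == "tau":
                tau = [float(v) for v in rest]
            elif key == "R":
                rows.append([float(v) for v in rest])
        return cls(scale, np.asarray(rows), np.asarray(tau), shared,
                   np.nan, np.nan, np.nan, np.nan)


def _shared_rows(cfg: MdsConfiguration, labels: list[str]) -> np.ndarray:
    idx = [cfg.labels.index(l) for l in labels]
    return cfg.coords[idx]


class ProcrustesAlignment(BaseEstimator):
    """Estimate the similarity transform mapping one configuration onto another.

    Parameters
    ----------
    zeta : int or None
        Number of axes over which to align.  ``None`` uses the largest
        dimensionality both configurations support.

    Attributes
    ----------
    scale_, rotation_, translation_ : the fitted (s, R, tau)
    shared_labels_ : anchor labels common to both configurations
    ssd_before_, ssd_after_ : anchor-coordinate squared discrepancy
    transform_ : ProcrustesTransform bundle of the above
    """

    def __init__(self, zeta: int | None = None):
        self.zeta = zeta

    def fit(self, cfgX: MdsConfiguration, cfgY: MdsConfiguration
            ) -> "ProcrustesAlignment":
        zeta = self.zeta or min(cfgX.n_axes, cfgY.n_axes)
        gamma = [l for l in cfgX.labels if l in set(cfgY.labels)]
        if len(gamma) < 2:
            raise ValueError(
                f"need at least 2 shared anchor populations, found {len(gamma)}"
            )
        X = _shared_rows(cfgX.truncated(zeta), gamma)
        Y = _shared_rows(cfgY.truncated(zeta), gamma)
        Xbar, Ybar = X.mean(axis=0), Y.mean(axis=0)
        Xc, Yc = X - Xbar, Y - Ybar
        normY = np.linalg.norm(Yc)
        if normY == 0:
            raise ValueError("anchor configuration of Y is degenerate (all points equal)")
        s = np.linalg.norm(Xc) / normY
        # R minimises ||Xc - Yc R||_F over orthogonal R (reflections allowed):
        # with Yc' Xc = U S V', the maximiser of tr(R' Yc' Xc) is R = U V'.
        U, _, Vt = np.linalg.svd(Yc.T @ Xc)
        R = U @ Vt
        tau = Xbar - s * Ybar @ R
        Yp = s * Y @ R + tau
        self.scale_ = float(s)
        self.rotation_ = R
        self.translation_ = tau
        self.shared_labels_ = gamma
        self.zeta_ = zeta
        self.ssd_before_ = float(np.sum((X - Y) ** 2))
        self.ssd_after_ = float(np.sum((X - Yp) ** 2))
        # signed bias of anchor pairwise distances, before and after calibration
        from scipy.spatial.distance import pdist

        dx, dy, dyp = pdist(X), pdist(Y), pdist(Yp)
        self.transform_ = ProcrustesTransform(
            self.scale_, R, tau, gamma,
            self.ssd_before_, self.ssd_after_,
            float(np.mean(dy - dx)), float(np.mean(dyp - dx)),
        )
        return self

    def transform(self, cfgY: MdsConfiguration) -> MdsConfiguration:
        return apply_procrustes(cfgY, self.transform_)

    def fit_transform(self, cfgX: MdsConfiguration, cfgY: MdsConfiguration
                      ) -> MdsConfiguration:
        return self.fit(cfgX, cfgY).transform(cfgY)


def fit_procrustes(cfgX: MdsConfiguration, cfgY: MdsConfiguration,
                   zeta: int | None = None) -> ProcrustesTransform:
    """Fit (s, R, tau) over shared labels; see :class:`ProcrustesAlignment`."""
    return ProcrustesAlignment(zeta=zeta).fit(cfgX, cfgY).transform_


def apply_procrustes(cfgY: MdsConfiguration, T: ProcrustesTransform
                     ) -> MdsConfiguration:
    """Map every row y of the configuration to ``s y R + tau``."""
    cfg = cfgY.truncated(T.zeta) if cfgY.n_axes != T.zeta else cfgY
    coords = T.scale_s * cfg.coords @ T.rotation_R + T.translation_tau
    return MdsConfiguration(
        list(cfg.labels), coords, cfg.eigenvalues,
        cfg.cumulative_explained, cfg.cumulative_explained_abs,
    )


def alignment_diagnostics(A: LabeledDistanceMatrix, Bx: LabeledDistanceMatrix
                          ) -> dict:
    """Distance-space discrepancy between two matrices over shared pairs.

    Over unordered shared pairs {i < j}: ``bias_mean`` is the mean of
    ``Bx - A``, ``bias_relative`` that mean divided by the mean of ``A``
    over the same pairs, ``ssd`` the sum of squared differences.
    """
    shared = [l for l in A.labels if l in set(Bx.labels)]
    if len(shared) < 2:
        raise ValueError("need at least 2 shared labels for diagnostics")
    a = A.submatrix(shared).d
    b = Bx.submatrix(shared).d
    iu = np.triu_indices(len(shared), k=1)
    diff = b[iu] - a[iu]
    mean_a = float(np.mean(a[iu]))
    return {
        "bias_mean": float(np.mean(diff)),
        "bias_relative": float(np.mean(diff) / mean_a) if mean_a != 0 else np.nan,
        "ssd": float(np.sum(diff**2)),
        "n_pairs": len(diff),
    }
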