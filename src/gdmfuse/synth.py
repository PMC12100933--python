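"""Synthetic data with the statistical structure the pipeline assumes.

Three generators cover the pipeline end to end:

* hierarchically structured allele frequencies under the Balding-Nichols
  drift model (ancestral frequency per locus, Beta-distributed clade and
  population frequencies whose spread is governed by Fst parameters);
* a pair of overlapping study distance matrices derived from one latent
  coordinate set, where the second study is distorted by a known
  similarity transform (scale, orthogonal rotation, translation) plus
  optional coordinate noise — so a Procrustes-recoverable ground truth
  exists by construction;
* per-population trait estimates (dry-matter-yield scale, kg DM/ha per
  harvest) with heterogeneous standard errors, plus endophyte effect
  tables, for the group estimators.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ortho_group

from .matrix import AlleleFrequencyTable, LabeledDistanceMatrix

__all__ = [
    "Distortion", "SyntheticTruth",
    "simulate_allele_frequencies", "simulate_latent_coords",
    "simulate_study_pair", "simulate_population_estimates",
    "structured_study_pair",
]


@dataclass
class Distortion:
    """A known similarity transform applied to the second study's coordinates."""

    scale: float = 1.0
    rotation: np.ndarray | None = None  # None = identity
    translation: np.ndarray | None = None  # None = zero
    coord_noise_sd: float = 0.0

    @classmethod
    def random(cls, dim: int, scale: float = 1.0, coord_noise_sd: float = 0.0,
               seed: int = 0) -> "Distortion":
        rng = np.random.default_rng(seed)
        R = ortho_group.rvs(dim, random_state=rng) if dim > 1 else np.array([[1.0]])
        tau = rng.normal(0.0, 1.0, size=dim)
        return cls(scale, R, tau, coord_noise_sd)


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated study pair."""

    latent_coords: np.ndarray
    labels: list[str]
    clade_labels: list[str] | None
    true_distance: LabeledDistanceMatrix
    study_split: tuple[list[str], list[str], list[str]]  # (A, B, shared)
    distortion: Distortion


def simulate_allele_frequencies(n_pops: int = 24, n_loci: int = 500,
                                n_clades: int = 3, fst_between: float = 0.10,
                                fst_within: float = 0.02, seed: int = 0
                                ) -> tuple[AlleleFrequencyTable, list[str]]:
    """Hierarchical allele frequencies under the Balding-Nichols model.

    Per locus the ancestral reference frequency is Uniform(0.05, 0.95);
    each clade draws its frequency from Beta with that mean and variance
    scaled by ``fst_between``; each population draws around its clade with
    ``fst_within``.  Returns the table and the clade label per population.
    """
    for name, f in (("fst_between", fst_between), ("fst_within", fst_within)):
        if not 0.0 < f < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1), got {f}")
    if n_clades < 1 or n_pops < n_clades:
        raise ValueError("need 1 <= n_clades <= n_pops")
    rng = np.random.default_rng(seed)

    def drift(p: np.ndarray, fst: float) -> np.ndarray:
        a = p * (1.0 - fst) / fst
        b = (1.0 - p) * (1.0 - fst) / fst
        return np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)

    ancestral = rng.uniform(0.05, 0.95, size=n_loci)
    clade_freq = np.stack([drift(ancestral, fst_between) for _ in range(n_clades)])
    clades = [f"clade{c + 1}" for c in range(n_clades)]
    assignment = [clades[i % n_clades] for i in range(n_pops)]
    freq = np.stack([
        drift(clade_freq[clades.index(a)], fst_within) for a in assignment
    ])
    table = AlleleFrequencyTable(
        [f"pop{i + 1:03d}" for i in range(n_pops)],
        [f"locus{j + 1:04d}" for j in range(n_loci)],
        freq,
    )
    return table, assignment


def simulate_latent_coords(n: int, dim: int = 2, n_clades: int = 3,
                           clade_spread: float = 3.0, within_spread: float = 1.0,
                           seed: int = 0) -> tuple[np.ndarray, list[str]]:
    """Clustered latent coordinates: Gaussian blobs, one per clade."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, clade_spread, size=(n_clades, dim))
    assignment = [i % n_clades for i in range(n)]
    coords = np.stack([
        centers[c] + rng.normal(0.0, within_spread, size=dim) for c in assignment
    ])
    return coords, [f"clade{c + 1}" for c in assignment]


def simulate_study_pair(truth_coords: np.ndarray, nA: int, nB: int, nShared: int,
                        distortion: Distortion | None = None, seed: int = 0,
                        labels: list[str] | None = None,
                        clade_labels: list[str] | None = None
                        ) -> tuple[LabeledDistanceMatrix, LabeledDistanceMatrix,
                                   SyntheticTruth]:
    """Two overlapping study matrices from one latent coordinate set.

    Study A measures the first ``nA`` populations' true pairwise norms;
    study B measures the last ``nB`` populations after its coordinates
    are scaled, rotated, translated and jittered per ``distortion`` —
    emulating an incompatible genotyping platform.  ``nShared``
    populations appear in both.
    """
    coords = np.asarray(truth_coords, dtype=float)
    n, dim = coords.shape
    if nShared > min(nA, nB) or nA + nB - nShared != n:
        raise ValueError(
            f"infeasible split: nA={nA}, nB={nB}, shared={nShared} for n={n}"
        )
    distortion = distortion or Distortion()
    rng = np.random.default_rng(seed)
    labels = labels or [f"pop{i + 1:03d}" for i in range(n)]

    a_labels = labels[:nA]
    b_labels = labels[nA - nShared:]
    true_d = LabeledDistanceMatrix(list(labels), squareform(pdist(coords)))

    A = true_d.submatrix(a_labels)
    R = distortion.rotation if distortion.rotation is not None else np.eye(dim)
    tau = (distortion.translation if distortion.translation is not None
           else np.zeros(dim))
    b_coords = distortion.scale * coords[nA - nShared:] @ R + tau
    if distortion.coord_noise_sd > 0:
        b_coords = b_coords + rng.normal(0.0, distortion.coord_noise_sd,
                                         size=b_coords.shape)
    B = LabeledDistanceMatrix(list(b_labels), squareform(pdist(b_coords)))
    truth = SyntheticTruth(
        coords, labels, clade_labels, true_d,
        (a_labels, b_labels, labels[nA - nShared:nA]), distortion,
    )
    return A, B, truth


def structured_study_pair(seed: int, n: int = 60, dim: int = 8,
                          n_clades: int = 6, clade_spread: float = 3.0,
                          within_spread: float = 1.2, scale: float = 1.5,
                          coord_noise_sd: float = 0.05,
                          shared_fraction: float = 0.2
                          ) -> tuple[LabeledDistanceMatrix,
                                     LabeledDistanceMatrix, SyntheticTruth]:
    """The package's standard structured benchmark pair.

    A scaled-down analogue of the two-study setting the pipeline targets:
    hierarchically structured populations in a moderately
    high-dimensional latent space, about a fifth of the populations
    shared between studies, and the second study distorted by a platform
    scale factor plus coordinate noise.
    """
    coords, clades = simulate_latent_coords(
        n, dim=dim, n_clades=n_clades, clade_spread=clade_spread,
        within_spread=within_spread, seed=seed,
    )
    nShared = round(shared_fraction * n)
    nA = (n + nShared) // 2
    nB = n + nShared - nA
    distortion = Distortion.random(dim, scale=scale,
                                   coord_noise_sd=coord_noise_sd, seed=seed)
    return simulate_study_pair(coords, nA, nB, nShared, distortion,
                               seed=seed, clade_labels=clades)


def simulate_population_estimates(clade_labels: list[str],
                                  clade_means: dict[str, float],
                                  within_sd: float = 30.0,
                                  se_low: float = 20.0, se_high: float = 60.0,
                                  endophyte_effects: dict[str, tuple[float, float]]
                                  | None = None,
                                  seed: int = 0,
                                  labels: list[str] | None = None
                                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population trait predictions with heterogeneous standard errors.

    ``P_i ~ Normal(clade mean, within_sd)`` and ``se_i ~ Uniform(se_low,
    se_high)``; an endophyte table of (effect, se) pairs is passed through.
    Returns (population table, endophyte table) as DataFrames.
    """
    if se_low <= 0:
        raise ValueError("se_low must be positive")
    rng = np.random.default_rng(seed)
    labels = labels or [f"pop{i + 1:03d}" for i in range(len(clade_labels))]
    pops = pd.DataFrame({
        "label": labels,
        "clade": clade_labels,
        "P": [rng.normal(clade_means[c], within_sd) for c in clade_labels],
        "se": rng.uniform(se_low, se_high, size=len(clade_labels)),
    })
    endo = pd.DataFrame(
        [{"name": k, "E": v[0], "se_E": v[1]}
         for k, v in (endophyte_effects or {}).items()]
    )
    return pops, endo
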