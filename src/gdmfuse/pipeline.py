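"""End-to-end composition: embed, calibrate, back-map, merge.

Convenience wrapper chaining the pipeline stages that turn two
incompatible study matrices into one merged matrix with structural
missingness, collecting the alignment diagnostics along the way.
"""

from __future__ import annotations

from dataclasses import dataclass

from .matrix import LabeledDistanceMatrix
from .mds import MdsConfiguration, classical_mds, distances_from_config, shared_dimension
from .merge import MergedMatrix, merge_matrices
from .procrustes import ProcrustesAlignment, alignment_diagnostics

__all__ = ["CalibrationResult", "calibrate_and_merge"]


@dataclass
class CalibrationResult:
    """Everything produced on the way from (A, B) to the merged matrix."""

    config_A: MdsConfiguration
    config_B: MdsConfiguration
    zeta: int
    aligner: ProcrustesAlignment
    B_calibrated: LabeledDistanceMatrix
    merged: MergedMatrix
    diagnostics_before: dict
    diagnostics_after: dict

    @property
    def ssd_reduction_percent(self) -> float:
        """Reduction of shared-pair SSD achieved by the calibration."""
        before = self.diagnostics_before["ssd"]
        after = self.diagnostics_after["ssd"]
        return 100.0 * (1.0 - after / before) if before > 0 else 0.0


def calibrate_and_merge(A: LabeledDistanceMatrix, B: LabeledDistanceMatrix,
                        zeta: int | None = None) -> CalibrationResult:
    """Embed both matrices, calibrate B onto A, back-map and merge.

    ``zeta`` defaults to the largest dimensionality both embeddings
    support.  Distance-space diagnostics compare A against the raw B
    embedding (before) and against the calibrated B' (after) over shared
    pairs.
    """
    cfgA = classical_mds(A)
    cfgB = classical_mds(B)
    z = zeta or shared_dimension(cfgA, cfgB)
    aligner = ProcrustesAlignment(zeta=z).fit(cfgA, cfgB)
    Bp = distances_from_config(aligner.transform(cfgB))
    raw_embed = distances_from_config(cfgB.truncated(z))
    return CalibrationResult(
        cfgA, cfgB, z, aligner, Bp, merge_matrices(A, Bp),
        alignment_diagnostics(A, raw_embed), alignment_diagnostics(A, Bp),
    )
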