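"""Distance trees and phenotype aggregation over genetic groups.

The completed distance matrix feeds an unrooted neighbor-joining tree,
and per-population trait predictions (dry matter yield, kg DM/ha per
harvest) are aggregated per genetic group by inverse-variance weighting:

    nu   = sum(w_i P_i) / sum(w_i),          w_i = 1 / se_i^2
    s.e. = sqrt( (1/k^2) sum(se_i^2) + sum(w_i (P_i - nu)^2) / sum(w_i) )

whose standard error combines the mean sampling variance of the member
predictions with the weighted dispersion of members around the group
value.  Populations without a trait prediction inherit their group's
estimate.  Host-endophyte combinations are scored additively:
``PE = mu + P + E`` with independent-error aggregation of the SEs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import LabeledDistanceMatrix

__all__ = [
    "PopulationEstimate", "EndophyteEffect", "GroupEstimate",
    "nj_tree", "group_estimate", "fill_missing_from_group",
    "combination_estimate", "combination_grid",
]


@dataclass
class PopulationEstimate:
    """A population's trait prediction with its standard error."""

    label: str
    P: float
    se: float
    provenance: str = "direct"

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"standard error must be positive for {self.label}")


@dataclass
class EndophyteEffect:
    """An endophyte strain's additive trait effect with its standard error."""

    name: str
    E: float
    se_E: float

    def __post_init__(self) -> None:
        if self.se_E < 0:
            raise ValueError(f"standard error must be nonnegative for {self.name}")


@dataclass
class GroupEstimate:
    """Inverse-variance weighted group trait value."""

    members: list[str]
    nu: float
    se_group: float
    k: int


def nj_tree(D: LabeledDistanceMatrix) -> str:
    """Unrooted neighbor-joining tree as a Newick string.

    Negative branch lengths (a known NJ artefact on non-additive input)
    are clamped to zero with the deficit transferred to the adjacent
    branch, preserving leaf-to-leaf path lengths where possible.
    """
    import skbio

    if not D.is_complete:
        raise ValueError("matrix has missing entries; impute before tree building")
    if D.n < 3:
        raise ValueError("need at least 3 populations for a tree")
    dm = skbio.DistanceMatrix(D.d, ids=D.labels)
    tree = skbio.tree.nj(dm, neg_as_zero=False)
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            parent = node.parent
            if parent is not None:
                for sib in parent.children:
                    if sib is not node and sib.length is not None:
                        sib.length += node.length
                        break
            node.length = 0.0
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


def group_estimate(members: Sequence[PopulationEstimate]) -> GroupEstimate:
    """Inverse-variance weighted trait value of a genetic group."""
    if not members:
        raise ValueError("empty group")
    P = np.array([m.P for m in members])
    se = np.array([m.se for m in members])
    w = 1.0 / se**2
    k = len(members)
    nu = float(np.sum(w * P) / np.sum(w))
    var = np.sum(se**2) / k**2 + np.sum(w * (P - nu) ** 2) / np.sum(w)
    return GroupEstimate([m.label for m in members], nu, float(np.sqrt(var)), k)


def fill_missing_from_group(all_labels: Sequence[str],
                            estimates: Sequence[PopulationEstimate],
                            group_assignments: Mapping[str, str],
                            group_estimates: Mapping[str, GroupEstimate]
                            ) -> tuple[list[PopulationEstimate], list[str]]:
    """Give unestimated populations their group's value and standard error.

    Populations that already carry an estimate are untouched.  Populations
    whose group has no estimate are returned in the unresolved list, never
    silently dropped.
    """
    have = {e.label: e for e in estimates}
    out: list[PopulationEstimate] = []
    unresolved: list[str] = []
    for label in all_labels:
        if label in have:
            out.append(have[label])
            continue
        group = group_assignments.get(label)
        ge = group_estimates.get(group) if group is not None else None
        if ge is None:
            unresolved.append(label)
            continue
        out.append(PopulationEstimate(label, ge.nu, ge.se_group,
                                      provenance="group_fallback"))
    return out, unresolved


def combination_estimate(mu: float, pop: PopulationEstimate,
                         endo: EndophyteEffect) -> tuple[float, float]:
    """Additive host-endophyte trait estimate ``PE = mu + P + E``.

    The standard error combines the two sources under independence:
    ``SE = sqrt(se_E^2 + se_P^2)``.
    """
    pe = mu + pop.P + endo.E
    se = float(np.sqrt(endo.se_E**2 + pop.se**2))
    return pe, se


def combination_grid(mu: float, pops: Sequence[PopulationEstimate],
                     endos: Sequence[EndophyteEffect]) -> pd.DataFrame:
    """Long-format grid of all host-endophyte combination estimates."""
    rows = []
    for p in pops:
        for e in endos:
            pe, se = combination_estimate(mu, p, e)
            rows.append({"population": p.label, "endophyte": e.name,
                         "PE": pe, "SE": se})
    return pd.DataFrame(rows)
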