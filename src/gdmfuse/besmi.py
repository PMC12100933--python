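"""Bootstrap Evaluation for Structural Missingness Imputation (BESMI).

Random cross-validation with scattered holdouts misrepresents the merged
matrix's failure mode: whole cross-study blocks are missing at once.
BESMI therefore simulates exactly that pattern — per replicate it draws
about a fifth of the labels from each study side, hides every observed
cell pairing a drawn A-side label with a drawn B-side label, re-imputes,
and scores the hidden cells with the coefficient of determination

    R^2 = 1 - sum((zhat - z)^2) / sum((z - zbar)^2)

over unordered held-out pairs.  Methods are ranked by mean R^2 across
replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .impute import ChainedDistanceImputer, PredictorSpec
from .merge import MergedMatrix, Provenance

__all__ = [
    "MaskPlan", "BesmiReport",
    "make_mask_plans", "apply_mask", "r_squared", "run_besmi",
]

logger = logging.getLogger(__name__)


@dataclass
class MaskPlan:
    """One replicate's simulated structural mask and its held-out truth."""

    replicate_id: int
    selected_A: list[str]
    selected_B: list[str]
    masked_cells: list[tuple[int, int]]  # unordered index pairs i < j
    held_out: dict = field(default_factory=dict)  # (i, j) -> true distance


@dataclass
class BesmiReport:
    """Per-(method, replicate) R^2 scores with per-method aggregates."""

    scores: pd.DataFrame  # columns: method, replicate, r2
    summary: pd.DataFrame  # columns: method, mean_r2, sd_r2, n_ok
    best_method: str

    def to_long_frame(self) -> pd.DataFrame:
        return self.scores.copy()


def make_mask_plans(M: MergedMatrix, n_replicates: int = 10,
                    mask_fraction: float = 0.2, seed: int = 0,
                    max_retries: int = 100) -> list[MaskPlan]:
    """Draw seeded structural masks over the observed cells of ``M``.

    Per replicate, ``round(mask_fraction * |side|)`` labels are drawn
    without replacement from each study side; the masked cells are all
    currently observed cells pairing a drawn A-side label with a drawn
    B-side label (the structural cross-block pattern).  A draw that would
    leave some label with no observed off-diagonal entry is retried.
    """
    rng = np.random.default_rng(seed)
    a_side, b_side = M.a_side_labels, M.b_side_labels
    nA = round(mask_fraction * len(a_side))
    nB = round(mask_fraction * len(b_side))
    idx = {l: k for k, l in enumerate(M.labels)}
    off = ~np.eye(M.n, dtype=bool)
    observed = ~M.missing_mask & off
    plans = []
    for rep in range(n_replicates):
        for attempt in range(max_retries):
            selA = sorted(rng.choice(a_side, size=nA, replace=False)) if nA else []
            selB = sorted(rng.choice(b_side, size=nB, replace=False)) if nB else []
            cells = set()
            for la in selA:
                for lb in selB:
                    if la == lb:
                        continue
                    i, j = idx[la], idx[lb]
                    if observed[i, j]:
                        cells.add((min(i, j), max(i, j)))
            # each label must keep at least one observed off-diagonal entry
            remaining = observed.copy()
            for i, j in cells:
                remaining[i, j] = remaining[j, i] = False
            if nA and nB and not cells:
                continue
            if remaining.sum(axis=1).min() >= 1 or not cells:
                plans.append(MaskPlan(rep, list(selA), list(selB), sorted(cells)))
                break
        else:
            raise RuntimeError(
                f"replicate {rep}: could not draw a mask leaving every label "
                f"with an observed entry after {max_retries} retries"
            )
    return plans


def apply_mask(M: MergedMatrix, plan: MaskPlan) -> MergedMatrix:
    """Hide the plan's cells (both triangle copies), recording the truth."""
    out = M.copy()
    plan.held_out = {}
    for i, j in plan.masked_cells:
        if i >= M.n or j >= M.n:
            raise ValueError(f"cell ({i}, {j}) outside matrix of size {M.n}")
        if np.isnan(M.values[i, j]):
            continue  # already missing: idempotent
        plan.held_out[(i, j)] = float(M.values[i, j])
        out.values[i, j] = out.values[j, i] = np.nan
        out.provenance[i, j] = out.provenance[j, i] = Provenance.STRUCTURAL_MISSING
    return out


def r_squared(actual: np.ndarray, imputed: np.ndarray) -> float:
    """Coefficient of determination of imputed vs held-out true distances."""
    actual = np.asarray(actual, dtype=float)
    imputed = np.asarray(imputed, dtype=float)
    if actual.shape != imputed.shape or actual.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    ss_tot = np.sum((actual - actual.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("actual values have zero variance; R^2 undefined")
    return float(1.0 - np.sum((imputed - actual) ** 2) / ss_tot)


def run_besmi(M: MergedMatrix, methods: list[PredictorSpec],
              plans: list[MaskPlan], max_iter: int = 10,
              rel_tol: float = 1e-4) -> BesmiReport:
    """Score every (method, mask replicate) pair and rank methods by mean R^2."""
    if not plans:
        raise ValueError("no mask plans supplied")
    rows = []
    for spec in methods:
        for plan in plans:
            masked = apply_mask(M, plan)
            try:
                imp = ChainedDistanceImputer(
                    method=spec.method, seed=spec.seed + plan.replicate_id,
                    max_iter=max_iter, rel_tol=rel_tol,
                    hyperparameters=spec.hyperparameters,
                ).fit(masked)
                pairs = sorted(plan.held_out)
                actual = np.array([plan.held_out[p] for p in pairs])
                imputed = np.array([imp.result_.d[p] for p in pairs])
                r2 = r_squared(actual, imputed)
                rows.append({"method": spec.method, "replicate": plan.replicate_id,
                             "r2": r2, "error": ""})
            except Exception as exc:  # one failure must not sink the sweep
                logger.warning("BESMI %s/rep%d failed: %s",
                               spec.method, plan.replicate_id, exc)
                rows.append({"method": spec.method, "replicate": plan.replicate_id,
                             "r2": np.nan, "error": str(exc)})
    scores = pd.DataFrame(rows)
    summary = (
        scores.groupby("method", sort=False)["r2"]
        .agg(mean_r2="mean", sd_r2="std", n_ok="count")
        .reset_index()
    )
    best = summary.loc[summary["mean_r2"].idxmax(), "method"]
    return BesmiReport(scores, summary, str(best))
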