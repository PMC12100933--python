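"""Chained column-wise regression imputation of structurally missing distances.

Each population column with missing distances is regressed on the
distances to all other populations, using the populations whose distance
to the target is observed as training rows.  Columns are visited in
ascending order of missing count; predictions made earlier in a sweep are
immediately available as features for later columns, and from the second
sweep onward each sweep's imputations are averaged with the previous
iterate (a damping recursion that stabilises the chain).  Observed cells
are never modified; imputed cells are finally averaged with their
transpose counterparts and clamped at zero.

The predictor menu (lasso, regression tree, random forest, KNN,
predictive mean matching and its weighted variant, random sampling, and
the column-mean baseline) is dispatched through :func:`fit_predict`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import LassoCV, LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

from .matrix import LabeledDistanceMatrix
from .merge import MergedMatrix, Provenance

__all__ = ["PredictorSpec", "fit_predict", "ChainedDistanceImputer", "chained_impute"]

logger = logging.getLogger(__name__)

METHODS = ("lasso", "rt", "rf", "knn", "pmm", "wpmm", "sample", "mean")


@dataclass
class PredictorSpec:
    """A prediction function choice for the chained imputer.

    ``hyperparameters`` override the method defaults (e.g. ``n_trees``,
    ``k``, ``n_donors``, ``cv_folds``); ``seed`` makes stochastic methods
    reproducible.
    """

    method: str = "lasso"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")


def _drop_constant(train_X: np.ndarray, query_X: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    keep = train_X.std(axis=0) > 0
    if not keep.any():  # fully degenerate: keep one column, models reduce to mean
        keep[0] = True
    return train_X[:, keep], query_X[:, keep]


def fit_predict(train_X: np.ndarray, train_y: np.ndarray, query_X: np.ndarray,
                spec: PredictorSpec, rng: np.random.Generator | None = None
                ) -> np.ndarray:
    """Fit the predictor named by ``spec`` and predict the query rows.

    Model-based methods with fewer than 2 training rows degrade to the
    mean baseline (logged).  Constant feature columns are dropped before
    fitting.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=float)
    query_X = np.atleast_2d(np.asarray(query_X, dtype=float))
    rng = rng or np.random.default_rng(spec.seed)
    hp = spec.hyperparameters
    method = spec.method
    n_train = len(train_y)
    if n_train == 0:
        raise ValueError("no training rows")
    if method != "mean" and n_train < 2:
        logger.warning("method %r downgraded to mean: %d training row(s)",
                       method, n_train)
        method = "mean"

    if method == "mean":
        return np.full(len(query_X), train_y.mean())
    if method == "sample":
        return rng.choice(train_y, size=len(query_X), replace=True)

    X, Q = _drop_constant(train_X, query_X)
    seed = int(rng.integers(2**31 - 1))
    if method == "lasso":
        cv = min(int(hp.get("cv_folds", 5)), n_train)
        model = LassoCV(cv=cv, alphas=int(hp.get("n_alphas", 30)),
                        eps=float(hp.get("alpha_eps", 1e-3)),
                        max_iter=int(hp.get("max_iter", 2000)),
                        random_state=seed)
        import warnings
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, train_y)
        return model.predict(Q)
    if method == "rt":
        model = DecisionTreeRegressor(
            min_samples_leaf=int(hp.get("min_leaf", 2)), random_state=seed
        )
        return model.fit(X, train_y).predict(Q)
    if method == "rf":
        model = RandomForestRegressor(
            n_estimators=int(hp.get("n_trees", 100)),
            max_features=hp.get("max_features", "sqrt"),
            min_samples_leaf=int(hp.get("min_leaf", 2)),
            random_state=seed, n_jobs=1,
        )
        return model.fit(X, train_y).predict(Q)
    if method == "knn":
        k = min(int(hp.get("k", 5)), n_train)
        model = KNeighborsRegressor(n_neighbors=k, weights="distance")
        return model.fit(X, train_y).predict(Q)
    if method in ("pmm", "wpmm"):
        model = LinearRegression().fit(X, train_y)
        fitted = model.predict(X)
        yhat = model.predict(Q)
        d = min(int(hp.get("n_donors", 5)), n_train)
        eps = float(hp.get("eps", 1e-6))
        out = np.empty(len(yhat))
        for q, v in enumerate(yhat):
            gaps = np.abs(fitted - v)
            donors = np.argsort(gaps, kind="stable")[:d]
            if method == "pmm":
                pick = rng.choice(donors)
            else:
                w = 1.0 / (gaps[donors] + eps)
                pick = rng.choice(donors, p=w / w.sum())
            out[q] = train_y[pick]
        return out
    raise AssertionError(f"unhandled method {method}")  # pragma: no cover


class ChainedDistanceImputer(BaseEstimator):
    """Complete a merged distance matrix by iterative chained regression.

    Parameters
    ----------
    method : str
        Predictor name (see :data:`METHODS`).
    seed : int
        Master seed; per-(iteration, column) streams are derived from it.
    max_iter : int
        Maximum number of sweeps over the missing columns.
    rel_tol : float
        Convergence threshold on the maximum relative change of imputed
        cells between sweeps.
    hyperparameters : dict or None
        Passed through to the predictor.

    Attributes
    ----------
    result_ : LabeledDistanceMatrix
        The completed, symmetrised, nonnegative matrix.
    provenance_ : ndarray
        Per-cell tags with imputed cells marked.
    n_iter_ : int
    converged_ : bool
    trace_ : list of per-iteration maximum relative change
    """

    def __init__(self, method: str = "lasso", seed: int = 0, max_iter: int = 10,
                 rel_tol: float = 1e-4, hyperparameters: dict | None = None):
        self.method = method
        self.seed = seed
        self.max_iter = max_iter
        self.rel_tol = rel_tol
        self.hyperparameters = hyperparameters

    def fit(self, M: MergedMatrix) -> "ChainedDistanceImputer":
        spec = PredictorSpec(self.method, self.hyperparameters or {}, self.seed)
        n = M.n
        mask = M.missing_mask
        off = ~np.eye(n, dtype=bool)
        observed_per_label = (~mask & off).sum(axis=1)
        starved = [M.labels[i] for i in np.where(observed_per_label == 0)[0]]
        if starved:
            raise ValueError(
                f"populations with no observed distances cannot be imputed: {starved}"
            )
        prov = M.provenance.copy()
        if not mask.any():
            self.result_ = LabeledDistanceMatrix(list(M.labels), M.values.copy())
            self.provenance_ = prov
            self.n_iter_, self.converged_, self.trace_ = 0, True, []
            return self

        W = M.values.copy()
        # cold start: column means of observed off-diagonal entries
        col_means = np.array([
            W[~mask[:, j] & off[:, j], j].mean() for j in range(n)
        ])
        W[mask] = np.broadcast_to(col_means, (n, n))[mask]

        # ascending missing count; stable sort breaks ties by label order
        miss_count = mask.sum(axis=0)
        cols = [j for j in np.argsort(miss_count, kind="stable") if miss_count[j] > 0]

        self.trace_ = []
        self.converged_ = False
        W_prev = W.copy()
        P = W.copy()  # per-column own predictions of the current sweep
        k = 0
        col_seeds = np.random.SeedSequence(spec.seed).spawn(len(cols))
        for k in range(1, self.max_iter + 1):
            # per-column streams are re-created identically each sweep so the
            # fitted models (CV folds, donor draws) admit a fixed point
            col_rngs = [np.random.default_rng(s) for s in col_seeds]
            for rng, j in zip(col_rngs, cols):
                feat = [c for c in range(n) if c != j]
                train_rows = np.where(~mask[:, j] & off[:, j])[0]
                pred_rows = np.where(mask[:, j] & off[:, j])[0]
                if len(pred_rows) == 0:
                    continue
                preds = fit_predict(
                    W[np.ix_(train_rows, feat)], W[train_rows, j],
                    W[np.ix_(pred_rows, feat)], spec, rng=rng,
                )
                P[pred_rows, j] = preds
                # propagate the freshest prediction to both triangle copies
                # so columns visited later in this sweep see it as a feature
                W[pred_rows, j] = preds
                W[j, pred_rows] = preds
            # each imputed cell ends the sweep as the average of the two
            # column models that predict it (one per triangle copy)
            W[mask] = 0.5 * (P + P.T)[mask]
            if k > 1:
                W[mask] = 0.5 * (W[mask] + W_prev[mask])
            # change relative to the matrix's distance scale (per-cell
            # denominators blow up at near-zero distances)
            scale = np.mean(M.values[~mask & off]) or 1.0
            delta = np.max(np.abs(W[mask] - W_prev[mask])) / scale
            self.trace_.append(float(delta))
            W_prev = W.copy()
            if delta < self.rel_tol:
                self.converged_ = True
                break
        if not self.converged_:
            logger.warning("chained imputation did not converge in %d sweeps "
                           "(last max relative change %.3g)", k, self.trace_[-1])
        self.n_iter_ = k

        # finalise: symmetrise imputed cells, clamp at zero, tag provenance
        sym = 0.5 * (W + W.T)
        W[mask] = np.maximum(sym[mask], 0.0)
        prov[mask] = Provenance.IMPUTED
        # conservation guard: observed cells bit-identical
        assert np.array_equal(W[~mask], M.values[~mask])
        self.result_ = LabeledDistanceMatrix(list(M.labels), W)
        self.provenance_ = prov
        return self

    def fit_transform(self, M: MergedMatrix) -> LabeledDistanceMatrix:
        return self.fit(M).result_


def chained_impute(M: MergedMatrix, spec: PredictorSpec | None = None,
                   max_iter: int = 10, rel_tol: float = 1e-4
                   ) -> tuple[LabeledDistanceMatrix, dict]:
    """Impute a merged matrix; returns the completed matrix and a trace dict."""
    spec = spec or PredictorSpec()
    imp = ChainedDistanceImputer(
        method=spec.method, seed=spec.seed, max_iter=max_iter,
        rel_tol=rel_tol, hyperparameters=spec.hyperparameters,
    ).fit(M)
    trace = {
        "n_iter": imp.n_iter_,
        "converged": imp.converged_,
        "max_rel_change": imp.trace_,
    }
    return imp.result_, trace
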