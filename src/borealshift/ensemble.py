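"""Bagged regression-tree ensemble with leaf-sample retention.

A bootstrap-aggregated ensemble of CART regression trees that keeps, for
every leaf of every tree, summary statistics of the training responses
routed there (with bootstrap multiplicity).  This enables the leaf-spread
uncertainty measure used throughout the cover and albedo mapping: for a
prediction, the training responses of the one leaf reached in each tree
are pooled across trees (concatenation with multiplicity) and the sample
standard deviation (n-1 denominator) of the pooled responses is reported.

Also provides the repeated k-fold cross-validated grid search used for
hyperparameter selection: the winning combination maximizes mean CV r^2,
with ties broken by lower RMSE, then lower RMSE standard deviation, then
grid order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

DEFAULT_GRID = {
    "n_trees": [100, 300],
    "max_features": ["sqrt", 1.0 / 3.0],
    "min_samples_split": [2, 5],
    "min_samples_leaf": [1, 3],
}


@dataclass
class ModelSpec:
    """A selected model configuration with its cross-validation statistics."""

    response: str
    mode: str  # three_season | one_season
    features: list[str]
    hyperparams: dict
    cv_stats: dict = field(default_factory=dict)
    seed: int = 0


class BaggedTreeEnsemble:
    """Bagged regression trees with per-leaf response retention.

    Parameters mirror the usual random-forest knobs: ``n_trees``,
    ``max_features`` per split ("sqrt" or a fraction), and the minimum
    samples per split / leaf.  Each tree is fit on a bootstrap resample;
    predictions average the per-tree leaf means, so they always lie within
    the training response range.
    """

    def __init__(
        self,
        n_trees: int = 100,
        max_features="sqrt",
        min_samples_split: int = 2,
        min_samples_leaf: int = 1,
        random_state: int = 0,
    ):
        self.n_trees = int(n_trees)
        self.max_features = max_features
        self.min_samples_split = int(min_samples_split)
        self.min_samples_leaf = int(min_samples_leaf)
        self.random_state = int(random_state)
        self.trees_: list[DecisionTreeRegressor] | None = None

    def get_params(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "max_features": self.max_features,
            "min_samples_split": self.min_samples_split,
            "min_samples_leaf": self.min_samples_leaf,
        }

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedTreeEnsemble":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError(f"bad training shapes X{X.shape}, y{y.shape}")
        if len(y) < 2:
            raise ValueError("need at least 2 training records")
        rng = np.random.default_rng(self.random_state)
        n = len(y)
        self.trees_ = []
        self._leaf_n: list[np.ndarray] = []
        self._leaf_sum: list[np.ndarray] = []
        self._leaf_sumsq: list[np.ndarray] = []
        self._leaf_min: list[np.ndarray] = []
        self._leaf_max: list[np.ndarray] = []
        self._boot_idx: list[np.ndarray] = []  # kept for introspection/oracles
        self._y_train = y.copy()
        # leaf sums are accumulated on mean-centred responses: variance is
        # shift-invariant and this avoids catastrophic cancellation
        self._y_shift = float(y.mean())
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            self._boot_idx.append(idx)
            tree = DecisionTreeRegressor(
                max_features=self.max_features,
                min_samples_split=self.min_samples_split,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            leaves = tree.apply(X[idx])
            n_nodes = tree.tree_.node_count
            yb = y[idx] - self._y_shift
            self._leaf_n.append(np.bincount(leaves, minlength=n_nodes).astype(float))
            self._leaf_sum.append(np.bincount(leaves, weights=yb, minlength=n_nodes))
            self._leaf_sumsq.append(
                np.bincount(leaves, weights=yb * yb, minlength=n_nodes)
            )
            lmin = np.full(n_nodes, np.inf)
            lmax = np.full(n_nodes, -np.inf)
            np.minimum.at(lmin, leaves, yb)
            np.maximum.at(lmax, leaves, yb)
            self._leaf_min.append(lmin)
            self._leaf_max.append(lmax)
            self.trees_.append(tree)
        return self

    def _check_fitted(self) -> None:
        if self.trees_ is None:
            raise RuntimeError("ensemble is not fitted")

    def predict(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        out = np.zeros(len(X))
        for tree in self.trees_:
            out += tree.predict(X)
        return out / len(self.trees_)

    def leaf_uncertainty(self, X: np.ndarray) -> np.ndarray:
        """Pooled leaf-spread standard deviation per row of X.

        Pools the training responses (with bootstrap multiplicity) of the
        leaf reached in each tree; returns the n-1 sample standard
        deviation of the pooled multiset, and 0 where the pooled count is 1
        or all pooled responses are identical.
        """
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        n_tot = np.zeros(len(X))
        s1 = np.zeros(len(X))
        s2 = np.zeros(len(X))
        vmin = np.full(len(X), np.inf)
        vmax = np.full(len(X), -np.inf)
        for tree, ln, ls, lq, lmin, lmax in zip(
            self.trees_, self._leaf_n, self._leaf_sum, self._leaf_sumsq,
            self._leaf_min, self._leaf_max,
        ):
            leaves = tree.apply(X)
            n_tot += ln[leaves]
            s1 += ls[leaves]
            s2 += lq[leaves]
            vmin = np.minimum(vmin, lmin[leaves])
            vmax = np.maximum(vmax, lmax[leaves])
        with np.errstate(invalid="ignore", divide="ignore"):
            var = (s2 - s1 * s1 / n_tot) / (n_tot - 1.0)
        var = np.where(n_tot > 1, np.maximum(var, 0.0), 0.0)
        # a pooled multiset with a single distinct value has exactly zero spread
        var = np.where(vmin == vmax, 0.0, var)
        return np.sqrt(var)

    def predict_with_uncertainty(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.predict(X), self.leaf_uncertainty(X)

    @property
    def feature_importances_(self) -> np.ndarray:
        self._check_fitted()
        return np.mean([t.feature_importances_ for t in self.trees_], axis=0)


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    hyperparams: dict,
    folds: int = 5,
    repeats: int = 3,
    seed: int = 0,
) -> dict:
    """Repeated k-fold CV; returns mean r^2, mean RMSE and RMSE sd.

    Each repeat reshuffles the fold partition with a derived seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 2 * folds:
        raise ValueError(
            f"{len(y)} records is too few for {folds}-fold CV; use fewer folds"
        )
    r2s, rmses = [], []
    for rep in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed + 1000 * rep)
        for tr, te in kf.split(X):
            if len(tr) < 2:
                raise ValueError("fold with <2 records; use fewer folds")
            model = BaggedTreeEnsemble(random_state=seed, **hyperparams)
            model.fit(X[tr], y[tr])
            pred = model.predict(X[te])
            r2s.append(_r2(y[te], pred))
            rmses.append(_rmse(y[te], pred))
    return {
        "mean_r2": float(np.mean(r2s)),
        "rmse": float(np.mean(rmses)),
        "rmse_sd": float(np.std(rmses, ddof=1)) if len(rmses) > 1 else 0.0,
    }


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: dict | None = None,
    folds: int = 5,
    repeats: int = 3,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Cross-validated grid search; returns (best hyperparams, cv stats).

    Selection maximizes mean CV r^2; ties break by lower RMSE, then lower
    RMSE sd, then first in grid order.  Deterministic given the seed.
    """
    grid = grid if grid is not None else DEFAULT_GRID
    keys = list(grid)
    combos = [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]
    if not combos:
        raise ValueError("hyperparameter grid is empty")
    best = None
    for i, combo in enumerate(combos):
        stats = cross_validate(X, y, combo, folds=folds, repeats=repeats, seed=seed)
        key = (-stats["mean_r2"], stats["rmse"], stats["rmse_sd"], i)
        if best is None or key < best[0]:
            best = (key, combo, stats)
    return best[1], best[2]
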