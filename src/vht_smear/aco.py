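"""Ant-colony-optimization wrapper feature selection.

Each ant assembles a subset of exactly ``k`` feature indices, sampling
without replacement with probability proportional to tau_i^alpha *
eta_i^beta, where tau is the learned pheromone level and eta a per-feature
Fisher discriminant score.  Subset fitness is the mean stratified 3-fold
cross-validated accuracy of a linear SVM restricted to the subset; after
each iteration the pheromone evaporates by (1 - rho) and the iteration-best
subset receives a deposit proportional to its fitness.  Pheromone levels are
clipped to fixed bounds, and the best subset found so far is retained
(elitist bookkeeping), so the best-fitness history is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

_EPS = 1e-12


@dataclass
class SelectionState:
    """Search state: pheromone/heuristic vectors, best subset and history."""

    pheromone: np.ndarray
    heuristic: np.ndarray
    best_subset: Tuple[int, ...] = ()
    best_fitness: float = 0.0
    history: List[float] = field(default_factory=list)


def heuristic_scores(X: np.ndarray, y: np.ndarray, eps: float = _EPS) -> np.ndarray:
    """Fisher discriminant ratio per feature.

    eta_i = (sample-weighted variance of class means) /
            (sample-weighted mean within-class variance + eps).
    Features identical across all samples score 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("heuristic_scores needs at least two classes")
    n = len(y)
    mu = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        w = len(Xc) / n
        between += w * (Xc.mean(axis=0) - mu) ** 2
        within += w * Xc.var(axis=0)
    eta = between / (within + eps)
    # features with no spread at all score exactly 0 (guard against roundoff)
    eta[X.var(axis=0) <= 1e-15 * (1.0 + mu ** 2)] = 0.0
    return eta


def construct_subset(state: SelectionState, k: int, alpha: float, beta: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Sample k distinct feature indices with probability ~ tau^alpha * eta^beta."""
    n = state.pheromone.size
    if k > n:
        raise ValueError(f"k={k} exceeds the number of features ({n})")
    if k == n:
        return np.arange(n)
    w = state.pheromone ** alpha * state.heuristic ** beta
    w = np.where(np.isfinite(w), w, 0.0) + _EPS  # floor keeps sampling feasible
    p = w / w.sum()
    return np.sort(rng.choice(n, size=k, replace=False, p=p))


def _default_fitness_model():
    return make_pipeline(StandardScaler(), LinearSVC(C=1.0, dual=True,
                                                     max_iter=5000, tol=1e-3))


class AntColonySelector(BaseEstimator, TransformerMixin):
    """ACO wrapper feature selector (sklearn transformer).

    Selects exactly ``k`` feature columns.  After ``fit``, ``support_`` holds
    the selected indices, ``state_`` the full search state and
    ``fitness_history_`` the (non-decreasing) best fitness per iteration.

    Parameters follow common ACO-for-feature-selection practice and are all
    tunable: ``ants`` subset constructions per iteration, ``iterations``
    rounds, ``alpha``/``beta`` pheromone/heuristic exponents, ``rho``
    evaporation rate, ``tau0`` initial pheromone and ``tau_bounds`` clipping
    range.
    """

    def __init__(self, k: int = 100, ants: int = 20, iterations: int = 30,
                 alpha: float = 1.0, beta: float = 1.0, rho: float = 0.2,
                 tau0: float = 1.0, tau_bounds: Tuple[float, float] = (0.01, 10.0),
                 cv: int = 3, seed: int = 0):
        self.k = k
        self.ants = ants
        self.iterations = iterations
        self.alpha = alpha
        self.beta = beta
        self.rho = rho
        self.tau0 = tau0
        self.tau_bounds = tau_bounds
        self.cv = cv
        self.seed = seed

    def _fitness(self, X, y, subset, cache: Dict[Tuple[int, ...], float]) -> float:
        key = tuple(int(i) for i in subset)
        if key not in cache:
            folds = StratifiedKFold(n_splits=self.cv, shuffle=False)
            scores = cross_val_score(_default_fitness_model(), X[:, subset], y,
                                     cv=folds, scoring="accuracy")
            cache[key] = float(scores.mean())
        return cache[key]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < self.cv:
            raise ValueError(
                f"stratified {self.cv}-fold CV infeasible: smallest class has "
                f"{counts.min()} samples")
        n_feat = X.shape[1]
        if self.k > n_feat:
            raise ValueError(f"k={self.k} exceeds {n_feat} features")
        rng = np.random.default_rng(self.seed)
        state = SelectionState(
            pheromone=np.full(n_feat, float(self.tau0)),
            heuristic=heuristic_scores(X, y),
        )
        lo, hi = self.tau_bounds
        cache: Dict[Tuple[int, ...], float] = {}
        for _ in range(self.iterations):
            iter_best: Tuple[float, np.ndarray] | None = None
            for _ in range(self.ants):
                subset = construct_subset(state, self.k, self.alpha, self.beta, rng)
                fit = self._fitness(X, y, subset, cache)
                if iter_best is None or fit > iter_best[0]:
                    iter_best = (fit, subset)
                if fit > state.best_fitness or not state.best_subset:
                    state.best_fitness = fit
                    state.best_subset = tuple(int(i) for i in subset)
            state.pheromone *= (1.0 - self.rho)
            state.pheromone[iter_best[1]] += iter_best[0]
            np.clip(state.pheromone, lo, hi, out=state.pheromone)
            state.history.append(state.best_fitness)
        self.state_ = state
        self.support_ = np.array(state.best_subset, dtype=int)
        self.fitness_history_ = list(state.history)
        return self

    def transform(self, X) -> np.ndarray:
        return np.asarray(X)[:, self.support_]


def select(X, y, k: int, ants: int = 20, iterations: int = 30,
           alpha: float = 1.0, beta: float = 1.0, rho: float = 0.2,
           seed: int = 0) -> SelectionState:
    """Run the ACO search and return the final :class:`SelectionState`."""
    sel = AntColonySelector(k=k, ants=ants, iterations=iterations, alpha=alpha,
                            beta=beta, rho=rho, seed=seed)
    sel.fit(X, y)
    return sel.state_
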