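"""Hybrid dipper-throated + grey-wolf (DGWO) wrapper feature selection.

Agents are points in the unit hypercube [0,1]^d; thresholding a position
at 0.5 yields a binary feature mask whose fitness is the cross-validated
classification error of a cheap reference classifier (nearest centroid on
the selected, per-fold standardized columns).  Each iteration draws
R ~ U(0,1): with R < 0.5 every agent takes a grey-wolf step towards the
three current leaders (alpha, beta, delta); otherwise every agent takes a
dipper-throated flying-bird step (velocity update towards its personal
guide and the global best).  The best-ever position and its mask are
returned with the (monotone, best-so-far) fitness trace.

Update rules:

grey wolf, per leader L in {alpha, beta, delta}::

    a = 2*l*r1 - l        (l shrinks linearly 2 -> 0)
    c = 2*r2
    d_L = |c * x_L - x|
    x_L' = x_L - a * d_L
    x(t+1) = (x_a' + x_b' + x_d') / 3

dipper-throated swimming bird::

    BL(t+1) = BL_best - c1 * |c2 * BL_best - BL|

dipper-throated flying bird::

    BS(t+1) = c3*BS + c4*r1*(BL_best - BL) + c5*r1*(BL_Gbest - BL)
    BL(t+1) = BL + BS(t+1)

All positions are clipped to [0,1] after every update.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .config import DGWOSettings
from .types import FeatureTable

__all__ = [
    "dto_swim_update",
    "dto_fly_update",
    "gwo_step",
    "binarize_position",
    "ClassificationErrorFitness",
    "fitness_classification_error",
    "SelectionResult",
    "DGWOSelector",
    "dgwo_select",
    "exhaustive_best_mask",
]


def _clip01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def dto_swim_update(
    position: np.ndarray, best: np.ndarray, c1: float, c2: float
) -> np.ndarray:
    """Swimming-bird move: BL_best is a fixed point of this map."""
    position = np.asarray(position, dtype=float)
    best = np.asarray(best, dtype=float)
    return _clip01(best - c1 * np.abs(c2 * best - position))


def dto_fly_update(
    position: np.ndarray,
    speed: np.ndarray,
    best: np.ndarray,
    gbest: np.ndarray,
    c3: float,
    c4: float,
    c5: float,
    r1: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Flying-bird move: momentum plus pulls toward the best and global best."""
    position = np.asarray(position, dtype=float)
    new_speed = (
        c3 * np.asarray(speed, dtype=float)
        + c4 * r1 * (np.asarray(best, dtype=float) - position)
        + c5 * r1 * (np.asarray(gbest, dtype=float) - position)
    )
    return new_speed, _clip01(position + new_speed)


def gwo_step(
    positions: np.ndarray,
    leaders: np.ndarray,
    l: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Grey-wolf siege step pulling every agent toward alpha/beta/delta.

    ``leaders`` is a (3, d) array of the current three best positions.
    Fresh r1, r2 are drawn per agent, per leader and per component.
    """
    positions = np.asarray(positions, dtype=float)
    leaders = np.asarray(leaders, dtype=float)
    if leaders.shape[0] != 3:
        raise ValueError("gwo_step needs exactly 3 leaders (alpha, beta, delta)")
    n, d = positions.shape
    r1 = rng.random((n, 3, d))
    r2 = rng.random((n, 3, d))
    a = 2.0 * l * r1 - l
    c = 2.0 * r2
    dist = np.abs(c * leaders[None, :, :] - positions[:, None, :])
    candidates = leaders[None, :, :] - a * dist
    return _clip01(candidates.mean(axis=1))


def binarize_position(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """mask_j = 1 iff position_j > threshold (strict)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    return (np.asarray(position, dtype=float) > threshold).astype(int)


class ClassificationErrorFitness:
    """Stratified k-fold CV error of a nearest-centroid reference classifier.

    Folds are fixed at construction (fold seed), so every mask is scored
    on identical splits — a requirement for comparing masks, and for the
    exhaustive oracle to be a true lower bound.  Selected columns are
    standardized with per-training-fold statistics.  The empty mask
    scores 1.0 by convention.
    """

    def __init__(self, table: FeatureTable, k: int = 3, fold_seed: int = 0):
        if table.labels is None:
            raise ValueError("fitness requires a labelled feature table")
        classes = np.unique(table.labels)
        if classes.size < 2:
            raise ValueError("fitness requires at least two classes")
        self.X = table.values
        self.y = table.labels
        self.classes = classes
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
        self.folds = list(skf.split(self.X, self.y))

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != (self.X.shape[1],):
            raise ValueError("mask length must equal feature count")
        if not mask.any():
            return 1.0
        Xs = self.X[:, mask]
        errors = 0
        for train, test in self.folds:
            mu = Xs[train].mean(axis=0)
            sd = Xs[train].std(axis=0)
            sd[sd < 1e-12] = 1.0
            Xtr = (Xs[train] - mu) / sd
            Xte = (Xs[test] - mu) / sd
            centroids = np.stack(
                [Xtr[self.y[train] == cls].mean(axis=0) for cls in self.classes]
            )
            d2 = ((Xte[:, None, :] - centroids[None]) ** 2).sum(axis=2)
            pred = self.classes[np.argmin(d2, axis=1)]
            errors += int(np.sum(pred != self.y[test]))
        return errors / len(self.y)


def fitness_classification_error(
    mask: np.ndarray,
    table: FeatureTable,
    k: int = 3,
    fold_seed: int = 0,
    evaluator: Callable[[np.ndarray], float] | None = None,
) -> float:
    """CV classification error of a mask; pluggable evaluator."""
    if evaluator is None:
        evaluator = ClassificationErrorFitness(table, k=k, fold_seed=fold_seed)
    return evaluator(np.asarray(mask))


@dataclass
class SelectionResult:
    mask: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    fitness_trace: list[float] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return int(np.sum(self.mask))


class DGWOSelector(BaseEstimator):
    """DGWO wrapper feature selector (sklearn-style).

    fit(X, y) runs the hybrid search; ``support_`` is the selected-feature
    boolean mask, ``transform`` keeps the selected columns.
    """

    def __init__(
        self,
        n_agents: int = 10,
        max_iter: int = 30,
        random_state: int = 0,
        c1_start: float = 2.0,
        c1_end: float = 0.0,
        c3_start: float = 0.9,
        c3_end: float = 0.4,
        c4: float = 1.5,
        c5: float = 1.5,
        switch_threshold: float = 0.5,
        binarize_threshold: float = 0.5,
        cv_folds: int = 3,
        algorithm1_position_update: bool = False,
        evaluator: Callable[[np.ndarray], float] | None = None,
    ):
        self.n_agents = n_agents
        self.max_iter = max_iter
        self.random_state = random_state
        self.c1_start = c1_start
        self.c1_end = c1_end
        self.c3_start = c3_start
        self.c3_end = c3_end
        self.c4 = c4
        self.c5 = c5
        self.switch_threshold = switch_threshold
        self.binarize_threshold = binarize_threshold
        self.cv_folds = cv_folds
        self.algorithm1_position_update = algorithm1_position_update
        self.evaluator = evaluator

    def _make_evaluator(self, X, y) -> Callable[[np.ndarray], float]:
        if self.evaluator is not None:
            return self.evaluator
        table = FeatureTable(
            [str(i) for i in range(len(X))],
            [f"f{j}" for j in range(X.shape[1])],
            X,
            y,
        )
        return ClassificationErrorFitness(table, k=self.cv_folds, fold_seed=0)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        d = X.shape[1]
        if d == 0:
            raise ValueError("no features to select from")
        if self.n_agents < 4:
            raise ValueError("need at least 4 agents (3 leaders + a follower)")
        evaluate = self._make_evaluator(X, y)
        rng = np.random.default_rng(self.random_state)

        positions = rng.random((self.n_agents, d))
        speeds = np.zeros((self.n_agents, d))

        def score_all(pos: np.ndarray) -> np.ndarray:
            return np.array(
                [evaluate(binarize_position(p, self.binarize_threshold)) for p in pos]
            )

        fitness = score_all(positions)

        best_fit = np.inf
        best_pos = positions[0].copy()
        best_nsel = d + 1
        trace: list[float] = []

        def consider(pos: np.ndarray, fits: np.ndarray) -> None:
            nonlocal best_fit, best_pos, best_nsel
            for i in range(len(pos)):  # lower agent index wins ties
                nsel = int(binarize_position(pos[i], self.binarize_threshold).sum())
                if fits[i] < best_fit or (fits[i] == best_fit and nsel < best_nsel):
                    best_fit = float(fits[i])
                    best_pos = pos[i].copy()
                    best_nsel = nsel

        consider(positions, fitness)

        denom = max(self.max_iter - 1, 1)
        for t in range(self.max_iter):
            frac = t / denom
            c1 = self.c1_start + (self.c1_end - self.c1_start) * frac
            c3 = self.c3_start + (self.c3_end - self.c3_start) * frac
            l = 2.0 * (1.0 - frac)
            R = rng.random()
            if R < self.switch_threshold:
                order = np.argsort(fitness, kind="stable")
                leaders = positions[order[:3]]
                positions = gwo_step(positions, leaders, l, rng)
            else:
                pbest = best_pos  # guide toward the incumbent best
                for i in range(self.n_agents):
                    r1 = rng.random()
                    new_speed = (
                        c3 * speeds[i]
                        + self.c4 * r1 * (pbest - positions[i])
                        + self.c5 * r1 * (best_pos - positions[i])
                    )
                    speeds[i] = new_speed
                    if self.algorithm1_position_update:
                        z, r2, r3 = rng.random(3)
                        positions[i] = _clip01(
                            r1 + z * r2 + (1 - z) * r3 + new_speed
                        )
                    else:
                        positions[i] = _clip01(positions[i] + new_speed)
                _ = c1  # c1/c2 drive the swim move, used in pure-DTO mode
            fitness = score_all(positions)
            consider(positions, fitness)
            trace.append(best_fit)

        self.n_features_in_ = d
        self.best_position_ = best_pos
        self.best_fitness_ = float(best_fit)
        self.support_ = binarize_position(best_pos, self.binarize_threshold).astype(bool)
        self.fitness_trace_ = trace
        self.n_selected_ = int(self.support_.sum())
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X)[:, self.support_]

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


def dgwo_select(table: FeatureTable, config: DGWOSettings | None = None,
                seed: int = 0,
                evaluator: Callable[[np.ndarray], float] | None = None) -> SelectionResult:
    """Run DGWO selection on a labelled feature table."""
    if table.labels is None:
        raise ValueError("dgwo_select requires a labelled table")
    config = config or DGWOSettings()
    sel = DGWOSelector(
        n_agents=config.n_agents,
        max_iter=config.max_iter,
        random_state=seed,
        c1_start=config.c1_start,
        c1_end=config.c1_end,
        c3_start=config.c3_start,
        c3_end=config.c3_end,
        c4=config.c4,
        c5=config.c5,
        switch_threshold=config.switch_threshold,
        binarize_threshold=config.binarize_threshold,
        cv_folds=config.cv_folds,
        algorithm1_position_update=config.algorithm1_position_update,
        evaluator=evaluator,
    ).fit(table.values, table.labels)
    return SelectionResult(
        mask=sel.support_.astype(int),
        best_position=sel.best_position_,
        best_fitness=sel.best_fitness_,
        fitness_trace=sel.fitness_trace_,
    )


def exhaustive_best_mask(
    table: FeatureTable,
    evaluator: Callable[[np.ndarray], float] | None = None,
) -> tuple[np.ndarray, float]:
    """Enumerate every nonempty mask; ties go to fewer features, then
    lexicographic order.  Refuses more than 16 features."""
    d = table.n_features
    if d > 16:
        raise ValueError(f"exhaustive search refused for d={d} > 16")
    if evaluator is None:
        evaluator = ClassificationErrorFitness(table)
    best_mask: np.ndarray | None = None
    best_fit = np.inf
    for size in range(1, d + 1):
        for idx in combinations(range(d), size):
            mask = np.zeros(d, dtype=int)
            mask[list(idx)] = 1
            fit = evaluator(mask)
            if fit < best_fit:
                best_fit = float(fit)
                best_mask = mask
    assert best_mask is not None
    return best_mask, best_fit
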