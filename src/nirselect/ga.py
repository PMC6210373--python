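"""Genetic-algorithm wrapper selection of a fixed-size PC subset.

An individual is a binary mask over the candidate principal components
(default 25) with fixed cardinality k.  Fitness is the cross-validated
prediction accuracy of the decision-tree RBF-SVM trained on the masked
score columns.  Selection is fitness-proportionate (roulette wheel),
reproduction uses one-point crossover and uniform per-bit mutation, and a
repair operator restores cardinality k after every variation.  The best
individual is carried over unchanged (elitism), which makes the
best-fitness trace non-decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .svm import SVMParams, TreeSVM

__all__ = [
    "GAConfig",
    "GATrace",
    "random_mask",
    "repair_mask",
    "roulette_select",
    "crossover_one_point",
    "mutate_uniform",
    "evaluate_fitness",
    "run_ga",
    "GeneticFeatureSelector",
]

logger = logging.getLogger(__name__)


@dataclass
class GAConfig:
    """Run parameters of the genetic search.

    Defaults follow the study conditions: population 200, at most 100
    generations, crossover probability 0.6, per-bit mutation probability
    0.01.  `k` is the fixed subset cardinality.  The run also stops early
    when the best fitness has not improved by more than `stagnation_tol`
    for `stagnation_generations` consecutive generations.
    """

    k: int = 14
    pop_size: int = 200
    max_generations: int = 100
    p_crossover: float = 0.6
    p_mutation: float = 0.01
    elitism_count: int = 1
    stagnation_generations: int = 20
    stagnation_tol: float = 1e-6
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 4 or self.pop_size % 2:
            raise ValueError(f"pop_size must be even and >= 4, got {self.pop_size}")
        if not 0 < self.p_crossover <= 1:
            raise ValueError(f"p_crossover must be in (0, 1], got {self.p_crossover}")
        if not 0 <= self.p_mutation < 1:
            raise ValueError(f"p_mutation must be in [0, 1), got {self.p_mutation}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.elitism_count < 0 or self.elitism_count >= self.pop_size:
            raise ValueError("elitism_count must be in [0, pop_size)")


@dataclass
class GATrace:
    """Per-generation record of the search."""

    best_fitness: np.ndarray
    mean_fitness: np.ndarray
    best_masks: np.ndarray  # (n_generations, n_candidates), best-so-far each gen
    n_evaluations: int = 0

    @property
    def n_generations(self) -> int:
        return len(self.best_fitness)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(self.n_generations),
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
                "best_mask": ["".join(map(str, m)) for m in self.best_masks],
            }
        )


def random_mask(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random 0/1 mask of length n with exactly k ones."""
    mask = np.zeros(n, dtype=np.int8)
    mask[rng.choice(n, size=k, replace=False)] = 1
    return mask


def repair_mask(mask: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Restore cardinality k by randomly clearing surplus / setting missing bits."""
    mask = np.asarray(mask, dtype=np.int8).copy()
    s = int(mask.sum())
    if s > k:
        on = np.flatnonzero(mask)
        mask[rng.choice(on, size=s - k, replace=False)] = 0
    elif s < k:
        off = np.flatnonzero(mask == 0)
        mask[rng.choice(off, size=k - s, replace=False)] = 1
    return mask


def roulette_select(
    fitnesses: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Fitness-proportionate sampling of parent indices (with replacement).

    All fitnesses must be non-negative; if every fitness is zero the draw
    falls back to uniform selection (logged).
    """
    f = np.asarray(fitnesses, dtype=float)
    if np.any(f < 0):
        raise ValueError("fitnesses must be non-negative")
    total = f.sum()
    if total == 0:
        logger.warning("all fitnesses are zero; falling back to uniform selection")
        p = np.full(f.size, 1.0 / f.size)
    else:
        p = f / total
    return rng.choice(f.size, size=n_draws, replace=True, p=p)


def crossover_one_point(
    a: np.ndarray,
    b: np.ndarray,
    rng: np.random.Generator,
    p_crossover: float = 1.0,
    k: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exchange the tails beyond a uniform cut point, then repair.

    With probability ``1 - p_crossover`` the parents are returned
    unchanged.  If `k` is given, both children are repaired to that
    cardinality.
    """
    a = np.asarray(a, dtype=np.int8)
    b = np.asarray(b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("parents must have equal length")
    if rng.random() >= p_crossover:
        return a.copy(), b.copy()
    cut = int(rng.integers(1, a.size)) if a.size > 1 else 0
    c1 = np.concatenate([a[:cut], b[cut:]])
    c2 = np.concatenate([b[:cut], a[cut:]])
    if k is not None:
        c1 = repair_mask(c1, k, rng)
        c2 = repair_mask(c2, k, rng)
    return c1, c2


def mutate_uniform(
    mask: np.ndarray,
    rng: np.random.Generator,
    p_mutation: float = 0.01,
    k: int | None = None,
) -> np.ndarray:
    """Flip each bit independently with probability `p_mutation`, then repair."""
    mask = np.asarray(mask, dtype=np.int8)
    flips = rng.random(mask.size) < p_mutation
    out = np.where(flips, 1 - mask, mask).astype(np.int8)
    if k is not None:
        out = repair_mask(out, k, rng)
    return out


def evaluate_fitness(
    mask,
    X,
    y,
    params: SVMParams = SVMParams(),
    cv_folds: int = 5,
    seed: int = 0,
    split_policy: str = "centroid",
    tol: float = 1e-3,
) -> float:
    """Stratified k-fold cross-validated accuracy of the tree SVM on masked columns.

    Deterministic given (mask, data, params, seed): the fold assignment is
    seeded, the SVM solver and tree construction are deterministic.  The
    solver tolerance defaults to libsvm's 1e-3 here — accuracy estimates
    are insensitive to it and the GA evaluates thousands of masks.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no components")
    X = np.asarray(X, dtype=float)[:, mask]
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < cv_folds:
        raise ValueError(
            f"every class needs >= cv_folds={cv_folds} samples "
            f"(smallest class has {counts.min()})"
        )
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        model = TreeSVM(C=params.C, sigma=params.sigma, split_policy=split_policy,
                        tol=tol)
        model.fit(X[tr], y[tr])
        correct += int(np.sum(model.predict(X[te]) == y[te]))
    return correct / y.size


def run_ga(
    X,
    y,
    params: SVMParams | None,
    cfg: GAConfig,
    fitness_fn=None,
    n_candidates: int | None = None,
    split_policy: str = "centroid",
) -> tuple[np.ndarray, GATrace]:
    """Run the genetic search; returns the best-ever mask and the full trace.

    `fitness_fn(mask) -> float` may be injected (e.g. for testing against
    an exhaustive oracle); by default fitness is the cross-validated
    accuracy of the tree SVM on the masked columns of `X`.  Fitness values
    are cached by mask bits, so revisited individuals are not re-evaluated.
    The whole trace is a deterministic function of `cfg.seed`.
    """
    if fitness_fn is None:
        if X is None or y is None:
            raise ValueError("X and y are required unless fitness_fn is injected")
        X = np.asarray(X, dtype=float)
        n = X.shape[1] if n_candidates is None else n_candidates
        p = params if params is not None else SVMParams()

        def fitness_fn(mask):
            return evaluate_fitness(
                mask, X, y, p, cv_folds=cfg.cv_folds, seed=cfg.seed,
                split_policy=split_policy,
            )
    else:
        if n_candidates is None:
            if X is None:
                raise ValueError("n_candidates required with an injected fitness_fn")
            n = np.asarray(X).shape[1]
        else:
            n = n_candidates
    if cfg.k > n:
        raise ValueError(f"k={cfg.k} infeasible with {n} candidates")

    rng = np.random.default_rng(cfg.seed)
    cache: dict[bytes, float] = {}
    n_evals = 0

    def fitness(mask: np.ndarray) -> float:
        nonlocal n_evals
        key = mask.tobytes()
        if key not in cache:
            cache[key] = float(fitness_fn(mask))
            n_evals += 1
        return cache[key]

    pop = [random_mask(n, cfg.k, rng) for _ in range(cfg.pop_size)]
    best_mask = pop[0].copy()
    best_fit = -np.inf
    best_hist, mean_hist, mask_hist = [], [], []
    stall = 0

    for _ in range(cfg.max_generations):
        fits = np.array([fitness(m) for m in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit + cfg.stagnation_tol:
            stall = 0
        else:
            stall += 1
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = pop[gen_best].copy()
        best_hist.append(best_fit)
        mean_hist.append(float(fits.mean()))
        mask_hist.append(best_mask.copy())
        if stall >= cfg.stagnation_generations:
            break

        parents = roulette_select(fits, cfg.pop_size, rng)
        children: list[np.ndarray] = []
        for i in range(0, cfg.pop_size, 2):
            c1, c2 = crossover_one_point(
                pop[parents[i]], pop[parents[i + 1]], rng,
                p_crossover=cfg.p_crossover, k=cfg.k,
            )
            children.append(mutate_uniform(c1, rng, cfg.p_mutation, k=cfg.k))
            children.append(mutate_uniform(c2, rng, cfg.p_mutation, k=cfg.k))
        # elitism: best-ever individuals replace the first children
        for e in range(cfg.elitism_count):
            children[e] = best_mask.copy()
        pop = children

    trace = GATrace(
        best_fitness=np.asarray(best_hist),
        mean_fitness=np.asarray(mean_hist),
        best_masks=np.asarray(mask_hist, dtype=np.int8),
        n_evaluations=n_evals,
    )
    return best_mask, trace


class GeneticFeatureSelector(SelectorMixin, BaseEstimator):
    """sklearn-style transformer wrapping :func:`run_ga`.

    ``fit(X, y)`` runs the genetic search over the columns of X (PC
    scores); ``transform`` keeps the selected columns.  Composes with
    sklearn pipelines and model selection.
    """

    def __init__(
        self,
        k: int = 14,
        C: float = 2.0,
        sigma: float = 2.0,
        pop_size: int = 200,
        max_generations: int = 100,
        p_crossover: float = 0.6,
        p_mutation: float = 0.01,
        elitism_count: int = 1,
        stagnation_generations: int = 20,
        cv_folds: int = 5,
        split_policy: str = "centroid",
        random_state: int = 0,
    ):
        self.k = k
        self.C = C
        self.sigma = sigma
        self.pop_size = pop_size
        self.max_generations = max_generations
        self.p_crossover = p_crossover
        self.p_mutation = p_mutation
        self.elitism_count = elitism_count
        self.stagnation_generations = stagnation_generations
        self.cv_folds = cv_folds
        self.split_policy = split_policy
        self.random_state = random_state

    def _make_config(self) -> GAConfig:
        return GAConfig(
            k=self.k,
            pop_size=self.pop_size,
            max_generations=self.max_generations,
            p_crossover=self.p_crossover,
            p_mutation=self.p_mutation,
            elitism_count=self.elitism_count,
            stagnation_generations=self.stagnation_generations,
            cv_folds=self.cv_folds,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mask, trace = run_ga(
            X, np.asarray(y), SVMParams(self.C, self.sigma), self._make_config(),
            split_policy=self.split_policy,
        )
        self.support_mask_ = mask.astype(bool)
        self.trace_ = trace
        self.best_fitness_ = float(trace.best_fitness[-1])
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_mask_")
        return self.support_mask_
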