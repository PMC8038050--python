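"""Descriptor-pool pruning and GA-MLR subset search.

Objective feature selection (OFS) removes constant, near-constant and highly
inter-correlated columns without looking at model quality. Subjective feature
selection searches fixed-size descriptor subsets with a genetic algorithm
whose fitness is the leave-one-out Q² of the OLS fit, with an exhaustive
enumerator kept as the reference search, and a breaking-point rule that picks
the model size where the marginal Q² gain collapses.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .validation import MLRModel, fit_ols, loo_predictions

log = logging.getLogger(__name__)

__all__ = [
    "OFSReport", "GAConfig", "ModelCandidate", "BreakingPoint",
    "ofs_filter", "ga_mlr_search", "exhaustive_mlr_search", "breaking_point",
    "subset_q2_loo",
]


# ---------------------------------------------------------------------------
# objective feature selection
# ---------------------------------------------------------------------------

@dataclass
class OFSReport:
    removed_constant: list[str]
    removed_near_constant: list[str]
    removed_correlated: list[tuple[str, str, float]]  # (dropped, kept, |R|)
    surviving: list[str]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, DescriptorMatrix):
        return X.to_frame()
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def ofs_filter(X, near_const_frac: float = 0.95, corr_cut: float = 0.90,
               y=None):
    """Prune the descriptor pool: constants, near-constants, collinear pairs.

    Order of operations: zero-variance columns first, then columns whose
    modal value covers at least ``near_const_frac`` of the molecules, then
    greedy pairwise |Pearson R| pruning. When a pair exceeds ``corr_cut``
    the column with the smaller |correlation to y| is dropped if ``y`` is
    given, otherwise the later column in name order. Returns the filtered
    matrix (same type as the input) and a complete :class:`OFSReport`.
    """
    df = _as_frame(X)
    if len(df) < 2:
        raise ValueError("need at least 2 molecules")
    removed_constant = [c for c in df.columns if df[c].nunique() == 1]
    work = df.drop(columns=removed_constant)

    n = len(df)
    removed_near_constant = [
        c for c in work.columns
        if work[c].value_counts().iloc[0] / n >= near_const_frac
    ]
    work = work.drop(columns=removed_near_constant)

    removed_correlated: list[tuple[str, str, float]] = []
    if work.shape[1] >= 2:
        corr = work.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        y_corr = None
        if y is not None:
            yv = np.asarray(y, dtype=float)
            y_corr = {c: abs(np.corrcoef(work[c], yv)[0, 1]) for c in work.columns}
        alive = list(work.columns)
        while True:
            sub = corr.loc[alive, alive]
            r_max = sub.values.max()
            if r_max <= corr_cut:
                break
            i, j = np.unravel_index(sub.values.argmax(), sub.shape)
            a, b = sub.index[i], sub.columns[j]
            if y_corr is not None:
                drop, keep = (a, b) if y_corr[a] < y_corr[b] else (b, a)
            else:
                drop, keep = (b, a) if str(b) > str(a) else (a, b)
            removed_correlated.append((drop, keep, float(r_max)))
            alive.remove(drop)
            if len(alive) < 2:
                break
        work = work[alive]

    if work.shape[1] == 0:
        raise ValueError("empty descriptor pool")
    report = OFSReport(
        removed_constant=removed_constant,
        removed_near_constant=removed_near_constant,
        removed_correlated=removed_correlated,
        surviving=list(work.columns),
    )
    if isinstance(X, DescriptorMatrix):
        return X.subset(report.surviving), report
    return work, report


# ---------------------------------------------------------------------------
# subset fitness
# ---------------------------------------------------------------------------

def subset_q2_loo(arr: np.ndarray, y: np.ndarray, cols: tuple[int, ...]) -> float:
    """Leave-one-out Q² of the OLS fit on a column subset; -inf if singular."""
    try:
        y_loo = loo_predictions(arr[:, list(cols)], y)
    except np.linalg.LinAlgError:
        return -math.inf
    press = float(((y - y_loo) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    q2 = 1.0 - press / tss
    return q2 if math.isfinite(q2) else -math.inf


@dataclass
class GAConfig:
    """Fixed-cardinality subset GA: tournament(2) selection, uniform crossover
    on the membership mask repaired to the model size, single-member swap
    mutation, elitism of one."""

    model_size: int = 5
    population: int = 200
    generations: int = 10_000
    mutation_rate: float = 0.05
    crossover_rate: float = 0.5
    seed: int = 0
    fitness: str = "q2_loo"
    patience: int | None = None  # stop early if the best is stagnant this long

    def __post_init__(self) -> None:
        if self.model_size < 1:
            raise ValueError("model_size must be >= 1")
        for r in (self.mutation_rate, self.crossover_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.fitness != "q2_loo":
            raise ValueError("only the q2_loo fitness is supported")


@dataclass
class ModelCandidate:
    descriptor_names: list[str]
    fitness_q2loo: float
    fitted_model: MLRModel | None = None


def _prepare_xy(X, y) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    if isinstance(X, DescriptorMatrix):
        arr, names, ids = X.values, list(X.names), list(X.ids)
    elif isinstance(X, pd.DataFrame):
        arr, names, ids = X.to_numpy(dtype=float), list(X.columns), [str(i) for i in X.index]
    else:
        arr = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(arr.shape[1])]
        ids = [str(i) for i in range(arr.shape[0])]
    y = np.asarray(y, dtype=float)
    if len(y) != arr.shape[0]:
        raise ValueError("X rows and y are not aligned")
    return arr, y, names, ids


def _ranked_candidates(memo: dict[tuple[int, ...], float], arr, y, names, ids,
                       top_k: int) -> list[ModelCandidate]:
    ranked = sorted(memo.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    out = []
    for cols, fit in ranked:
        model = None
        if math.isfinite(fit):
            model = fit_ols(arr[:, list(cols)], y,
                            names=[names[c] for c in cols], ids=ids)
        out.append(ModelCandidate(descriptor_names=[names[c] for c in cols],
                                  fitness_q2loo=fit, fitted_model=model))
    return out


def exhaustive_mlr_search(X, y, model_size: int, top_k: int = 10,
                          max_combinations: int = 1_000_000) -> list[ModelCandidate]:
    """Enumerate every descriptor subset of the given size, ranked by Q²LOO."""
    arr, y, names, ids = _prepare_xy(X, y)
    n_comb = math.comb(arr.shape[1], model_size)
    if n_comb > max_combinations:
        raise ValueError(f"{n_comb} combinations exceed the budget {max_combinations}")
    memo = {cols: subset_q2_loo(arr, y, cols)
            for cols in itertools.combinations(range(arr.shape[1]), model_size)}
    return _ranked_candidates(memo, arr, y, names, ids, top_k)


def ga_mlr_search(X, y, config: GAConfig, top_k: int = 10) -> list[ModelCandidate]:
    """Genetic-algorithm search over fixed-size descriptor subsets.

    Fitness is the leave-one-out Q² of the OLS fit (so the search itself
    penalizes overfitting); singular designs score -inf and are never ranked
    above finite candidates. Deterministic for a fixed seed. Candidates are
    the distinct subsets visited, ranked by fitness.
    """
    arr, y, names, ids = _prepare_xy(X, y)
    n_desc = arr.shape[1]
    k = config.model_size
    if k > n_desc:
        raise ValueError("model_size exceeds the descriptor pool")
    if k == n_desc:
        cols = tuple(range(n_desc))
        memo = {cols: subset_q2_loo(arr, y, cols)}
        return _ranked_candidates(memo, arr, y, names, ids, top_k)

    rng = np.random.default_rng(config.seed)
    memo: dict[tuple[int, ...], float] = {}

    def fitness(cols: tuple[int, ...]) -> float:
        if cols not in memo:
            memo[cols] = subset_q2_loo(arr, y, cols)
        return memo[cols]

    def random_subset() -> tuple[int, ...]:
        return tuple(sorted(rng.choice(n_desc, size=k, replace=False)))

    def repair(members: set[int]) -> tuple[int, ...]:
        members = set(members)
        while len(members) > k:
            members.remove(int(rng.choice(sorted(members))))
        while len(members) < k:
            members.add(int(rng.integers(n_desc)))
        return tuple(sorted(members))

    pop = [random_subset() for _ in range(config.population)]
    fits = [fitness(c) for c in pop]
    best, best_fit = max(zip(pop, fits), key=lambda t: t[1]), None
    best, best_fit = best[0], best[1]
    stagnant = 0

    def tournament() -> tuple[int, ...]:
        i, j = rng.integers(len(pop)), rng.integers(len(pop))
        return pop[i] if fits[i] >= fits[j] else pop[j]

    for _ in range(config.generations):
        new_pop = [best]  # elitism
        while len(new_pop) < config.population:
            pa, pb = tournament(), tournament()
            if rng.random() < config.crossover_rate:
                sa, sb = set(pa), set(pb)
                common = sa & sb
                rest = sorted(sa ^ sb)
                child = set(common)
                for g in rest:
                    if rng.random() < 0.5:
                        child.add(g)
                child = set(repair(child))
            else:
                child = set(pa)
            if rng.random() < config.mutation_rate:
                out_gene = int(rng.choice(sorted(child)))
                pool = [g for g in range(n_desc) if g not in child]
                child.discard(out_gene)
                child.add(int(rng.choice(pool)))
            new_pop.append(tuple(sorted(child)))
        pop = new_pop
        fits = [fitness(c) for c in pop]
        gen_best, gen_fit = max(zip(pop, fits), key=lambda t: t[1])
        if gen_fit > best_fit:
            best, best_fit = gen_best, gen_fit
            stagnant = 0
        else:
            stagnant += 1
            if config.patience is not None and stagnant >= config.patience:
                break
    return _ranked_candidates(memo, arr, y, names, ids, top_k)


# ---------------------------------------------------------------------------
# breaking point
# ---------------------------------------------------------------------------

@dataclass
class BreakingPoint:
    size: int
    table: pd.DataFrame  # columns: size, q2, gain
    warning: str | None = None


def breaking_point(q2_by_size: dict[int, float], gain_ratio: float = 0.25) -> BreakingPoint:
    """Elbow of the Q²-vs-model-size curve.

    Returns the smallest size s (>= 2) after which the next marginal gain
    g(s -> s+1) falls below ``gain_ratio`` times the preceding gain
    g(s-1 -> s). Sizes must be consecutive from 1. If the curve never breaks
    (e.g. strictly linear growth) the largest size is returned with a
    "no elbow" warning; Q² dips (negative gains) are logged, not rejected.
    """
    sizes = sorted(q2_by_size)
    if len(sizes) < 3:
        raise ValueError("need at least 3 consecutive model sizes")
    if sizes != list(range(1, len(sizes) + 1)):
        raise ValueError("sizes must be consecutive starting at 1")
    q2 = [q2_by_size[s] for s in sizes]
    gains = [float("nan")] + [q2[i] - q2[i - 1] for i in range(1, len(q2))]
    for i in range(1, len(gains)):
        if gains[i] < 0:
            log.warning("Q2 dips between sizes %d and %d", sizes[i - 1], sizes[i])
    table = pd.DataFrame({"size": sizes, "q2": q2, "gain": gains})
    for s in range(2, len(sizes)):  # s indexes the size whose *next* gain we inspect
        g_prev, g_next = gains[s - 1], gains[s]
        if g_prev > 0 and g_next < gain_ratio * g_prev:
            return BreakingPoint(size=sizes[s - 1], table=table)
    log.warning("no elbow found; returning the largest size")
    return BreakingPoint(size=sizes[-1], table=table, warning="no elbow")
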