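"""Data-driven item-subset search: ant colony, genetic, and exhaustive.

Both heuristics search per subscale for a fixed-size subset of items:

* **Ant colony optimization** — ants sample k-subsets with probability
  proportional to per-item pheromone; subsets are scored by an objective
  (default: congeneric ordinal CFA fit, phi = mean(CFI, TLI) - RMSEA);
  pheromone evaporates each iteration and the iteration-best subset
  reinforces its members. The search stops early once the best subset's fit
  passes the stopping rule (strict CFI/TLI/RMSEA cutoffs by default).
* **Genetic algorithm** — chromosomes are fixed-size k-subsets; fitness is
  the subset's Cronbach's alpha; tournament selection (size 2), uniform
  subset crossover repaired to size k, swap mutation, elitism.
* **Exhaustive search** — enumerates every k-subset (guarded); serves as
  the optimality oracle for both heuristics on small pools.

All searches are fully reproducible under their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Callable, Mapping, Sequence

import numpy as np

from .cfa import (
    ACO_STOP_RULE,
    FitIndices,
    FitRule,
    baseline_model,
    fit_cfa_dwls,
    fit_indices,
    meets_fit_thresholds,
    polychoric_matrix,
)
from .errors import ParameterError, UndefinedStatisticError, ValidationError
from .item_bank import ItemBank, ResponseMatrix
from .semantic import SelectionResult

__all__ = [
    "ACOConfig",
    "GAConfig",
    "cronbach_alpha",
    "aco_abbreviate",
    "ga_abbreviate",
    "exhaustive_best_subset",
    "cfa_fit_objective",
    "alpha_objective",
]

log = logging.getLogger(__name__)

#: An objective maps an ordered tuple of item_ids to a scalar (higher = better).
Objective = Callable[[tuple[str, ...]], float]


def cronbach_alpha(responses: ResponseMatrix) -> float:
    """Cronbach's alpha on complete cases: (k/(k-1)) (1 - sum var_i / var_total).

    Sample variances use the n-1 denominator.
    """
    vals = responses.values
    if vals.shape[1] < 2:
        raise ParameterError("Cronbach's alpha needs at least 2 items")
    complete = vals[~np.isnan(vals).any(axis=1)]
    if complete.shape[0] < 3:
        raise UndefinedStatisticError(
            f"Cronbach's alpha needs >= 3 complete cases, have {complete.shape[0]}"
        )
    k = complete.shape[1]
    item_vars = complete.var(axis=0, ddof=1)
    total_var = complete.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedStatisticError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


@dataclass(frozen=True)
class ACOConfig:
    """Ant colony settings. ``evaporation`` is the fraction of pheromone
    removed per iteration (0.05 means 95% is retained)."""

    n_ants: int = 20
    max_iterations: int = 100
    evaporation: float = 0.05
    pheromone_init: float = 1.0
    stop_rule: FitRule = ACO_STOP_RULE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ants < 1:
            raise ValidationError("n_ants must be >= 1")
        if not (0.0 < self.evaporation < 1.0):
            raise ValidationError("evaporation must lie strictly in (0, 1)")
        if self.pheromone_init <= 0:
            raise ValidationError("pheromone_init must be positive")


@dataclass(frozen=True)
class GAConfig:
    """Genetic algorithm settings for fixed-size subset chromosomes."""

    population: int = 30
    generations: int = 60
    crossover_rate: float = 0.8
    mutation_rate: float = 0.2
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValidationError("population must be >= 2")
        if not (0 <= self.elitism < self.population):
            raise ValidationError("elitism must be in [0, population)")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")


_PHEROMONE_FLOOR = 1e-9  # keeps pheromone strictly positive


def cfa_fit_objective(
    responses: ResponseMatrix,
    bank: ItemBank,
    subscale: str,
    min_pairs: int = 50,
) -> Callable[[tuple[str, ...]], tuple[float, FitIndices]]:
    """Default ACO objective: single-factor DWLS CFA on the candidate subset.

    The polychoric matrix of the whole subscale pool is computed once and
    subset per candidate; the scalar score is phi = mean(CFI, TLI) - RMSEA
    (RMSEA of a saturated model counts as 0). Returns (score, fit indices).
    """
    pool = [it.item_id for it in bank.items_in(subscale)]
    poly_full = polychoric_matrix(
        responses.subset(pool), bank.n_categories, min_pairs=min_pairs
    )
    n = responses.n_persons
    cache: dict[frozenset, tuple[float, FitIndices]] = {}

    def objective(subset: tuple[str, ...]) -> tuple[float, FitIndices]:
        key = frozenset(subset)
        if key not in cache:
            sub = poly_full.subset([i for i in pool if i in key])
            model = fit_cfa_dwls(sub, {i: subscale for i in key}, n)
            fit = fit_indices(model, baseline_model(sub, n))
            tli = fit.tli if fit.tli is not None else fit.cfi
            rmsea = fit.rmsea if fit.rmsea is not None else 0.0
            score = (fit.cfi + tli) / 2.0 - rmsea
            cache[key] = (float(score), fit)
        return cache[key]

    return objective


def alpha_objective(responses: ResponseMatrix) -> Objective:
    """Internal-consistency objective: Cronbach's alpha of the subset."""

    cache: dict[frozenset, float] = {}

    def objective(subset: tuple[str, ...]) -> float:
        key = frozenset(subset)
        if key not in cache:
            cache[key] = cronbach_alpha(responses.subset(list(subset)))
        return cache[key]

    return objective


def _check_k(bank: ItemBank, k: int) -> None:
    for sub in bank.subscales:
        size = len(bank.items_in(sub))
        if k > size:
            raise ParameterError(f"k={k} exceeds subscale {sub!r} size {size}")


def aco_abbreviate(
    responses: ResponseMatrix,
    bank: ItemBank,
    k: int,
    cfg: ACOConfig | None = None,
    objective_factory: Callable[[str], Callable] | None = None,
) -> SelectionResult:
    """Ant-colony search for the best-fitting k-subset of each subscale.

    ``objective_factory(subscale)`` must return a callable scoring a subset;
    it may return either a bare scalar or a (scalar, FitIndices) pair — the
    stopping rule is only consulted when fit indices are available. The
    default objective is the congeneric CFA fit described in
    :func:`cfa_fit_objective`.
    """
    cfg = cfg or ACOConfig()
    _check_k(bank, k)
    if objective_factory is None:
        objective_factory = lambda sub: cfa_fit_objective(responses, bank, sub)

    selected: dict[str, tuple[str, ...]] = {}
    diagnostics: dict[str, object] = {}
    for si, sub in enumerate(bank.subscales):
        pool = [it.item_id for it in bank.items_in(sub)]
        objective = objective_factory(sub)
        rng = np.random.Generator(np.random.PCG64([cfg.seed, si]))
        tau = np.full(len(pool), float(cfg.pheromone_init))
        best_subset: tuple[str, ...] | None = None
        best_score = -np.inf
        best_fit: FitIndices | None = None
        trace: list[tuple[int, float, float]] = []
        converged = False
        failures: list[tuple[str, ...]] = []

        for it_no in range(1, cfg.max_iterations + 1):
            iter_best = None
            iter_best_score = -np.inf
            scores = []
            for _ in range(cfg.n_ants):
                probs = tau / tau.sum()
                idx = rng.choice(len(pool), size=k, replace=False, p=probs)
                subset = tuple(pool[i] for i in sorted(idx))
                try:
                    result = objective(subset)
                except Exception as exc:  # scored -inf, search continues
                    log.warning("objective failed on %s: %s", subset, exc)
                    failures.append(subset)
                    result = -np.inf
                if isinstance(result, tuple):
                    score, fit = result
                else:
                    score, fit = float(result), None
                scores.append(score)
                if score > iter_best_score:
                    iter_best_score = score
                    iter_best = (subset, fit)
            # evaporation then reinforcement by the iteration best
            tau *= 1.0 - cfg.evaporation
            if iter_best is not None and np.isfinite(iter_best_score):
                deposit = max(iter_best_score, 0.0)
                members = [pool.index(i) for i in iter_best[0]]
                tau[members] += deposit
            tau = np.maximum(tau, _PHEROMONE_FLOOR)
            if iter_best_score > best_score:
                best_score = iter_best_score
                best_subset, best_fit = iter_best
            finite = [s for s in scores if np.isfinite(s)]
            trace.append(
                (it_no, best_score, float(np.mean(finite)) if finite else np.nan)
            )
            if best_fit is not None and meets_fit_thresholds(best_fit, cfg.stop_rule)[0]:
                converged = True
                break

        if best_subset is None:
            raise ParameterError(
                f"ant colony found no scorable subset in subscale {sub!r}"
            )
        selected[sub] = best_subset
        diagnostics[sub] = {
            "score": best_score,
            "fit": best_fit.as_dict() if best_fit is not None else None,
            "converged": converged,
            "iterations": len(trace),
            "trace": trace,
            "n_objective_failures": len(failures),
        }
    return SelectionResult("aco", selected, diagnostics, seed=cfg.seed)


def _repair(subset: set, pool: Sequence[str], k: int, rng) -> tuple[str, ...]:
    """Force a chromosome back to exactly k distinct in-pool items."""
    chosen = [i for i in pool if i in subset]
    if len(chosen) > k:
        drop = rng.choice(len(chosen), size=len(chosen) - k, replace=False)
        chosen = [c for i, c in enumerate(chosen) if i not in set(drop.tolist())]
    elif len(chosen) < k:
        others = [i for i in pool if i not in subset]
        add = rng.choice(len(others), size=k - len(chosen), replace=False)
        chosen += [others[i] for i in add]
    return tuple(sorted(chosen, key=pool.index))


def ga_abbreviate(
    responses: ResponseMatrix,
    bank: ItemBank,
    k: int,
    cfg: GAConfig | None = None,
    fitness_factory: Callable[[str], Objective] | None = None,
    initial: Mapping[str, Sequence[tuple[str, ...]]] | None = None,
) -> SelectionResult:
    """Genetic-algorithm search maximizing subset internal consistency.

    With k fixed the "fewest items" half of the classical fitness is a
    constant, so fitness reduces to Cronbach's alpha of the candidate subset
    (override via ``fitness_factory``). ``initial`` may seed the starting
    population with specific chromosomes per subscale.
    """
    cfg = cfg or GAConfig()
    _check_k(bank, k)
    if fitness_factory is None:
        fitness_factory = lambda sub: alpha_objective(responses)

    selected: dict[str, tuple[str, ...]] = {}
    diagnostics: dict[str, object] = {}
    for si, sub in enumerate(bank.subscales):
        pool = [it.item_id for it in bank.items_in(sub)]
        fitness = fitness_factory(sub)
        rng = np.random.Generator(np.random.PCG64([cfg.seed, si, 7]))

        def evaluate(chrom: tuple[str, ...]) -> float:
            try:
                return float(fitness(chrom))
            except Exception as exc:
                log.warning("fitness failed on %s: %s", chrom, exc)
                return -np.inf

        popn = [
            tuple(sorted(c, key=pool.index))
            for c in (initial or {}).get(sub, [])
        ][: cfg.population]
        popn += [
            tuple(
                sorted(
                    (pool[i] for i in rng.choice(len(pool), size=k, replace=False)),
                    key=pool.index,
                )
            )
            for _ in range(cfg.population - len(popn))
        ]
        fits = np.array([evaluate(c) for c in popn])
        best_i = int(np.argmax(fits))
        best_subset, best_fitness = popn[best_i], float(fits[best_i])
        trace = [(0, best_fitness, float(np.mean(fits[np.isfinite(fits)])))]

        for gen in range(1, cfg.generations + 1):
            order = np.argsort(-fits)
            new_pop = [popn[i] for i in order[: cfg.elitism]]
            while len(new_pop) < cfg.population:
                parents = []
                for _ in range(2):  # tournament of size 2
                    a, b = rng.integers(0, cfg.population, size=2)
                    parents.append(popn[a] if fits[a] >= fits[b] else popn[b])
                if rng.random() < cfg.crossover_rate:
                    inter = set(parents[0]) & set(parents[1])
                    union = set(parents[0]) | set(parents[1])
                    child = _repair(
                        inter | set(
                            x for x in union - inter if rng.random() < 0.5
                        ),
                        pool, k, rng,
                    )
                else:
                    child = parents[0]
                if rng.random() < cfg.mutation_rate:  # swap one item out
                    inside = list(child)
                    outside = [i for i in pool if i not in child]
                    if outside:
                        inside[rng.integers(len(inside))] = outside[
                            rng.integers(len(outside))
                        ]
                        child = tuple(sorted(set(inside), key=pool.index))
                        child = _repair(set(child), pool, k, rng)
                new_pop.append(child)
            popn = new_pop
            fits = np.array([evaluate(c) for c in popn])
            gen_best = int(np.argmax(fits))
            if fits[gen_best] > best_fitness:
                best_fitness = float(fits[gen_best])
                best_subset = popn[gen_best]
            finite = fits[np.isfinite(fits)]
            trace.append(
                (gen, best_fitness, float(np.mean(finite)) if len(finite) else np.nan)
            )

        selected[sub] = best_subset
        diagnostics[sub] = {"fitness": best_fitness, "trace": trace}
    return SelectionResult("ga", selected, diagnostics, seed=cfg.seed)


def exhaustive_best_subset(
    responses: ResponseMatrix,
    bank: ItemBank,
    k: int,
    objective_factory: Callable[[str], Callable],
    guard: int = 10_000,
) -> SelectionResult:
    """Enumerate every k-subset per subscale and return the argmax.

    Ties break lexicographically by item order (the first-enumerated
    optimum wins). Refuses pools with more than ``guard`` candidate subsets.
    """
    _check_k(bank, k)
    selected: dict[str, tuple[str, ...]] = {}
    diagnostics: dict[str, object] = {}
    for sub in bank.subscales:
        pool = [it.item_id for it in bank.items_in(sub)]
        count = comb(len(pool), k)
        if count > guard:
            raise ParameterError(
                f"subscale {sub!r}: {count} candidate subsets exceed the "
                f"exhaustive-search guard of {guard}"
            )
        objective = objective_factory(sub)
        best_subset = None
        best_score = -np.inf
        for combo in combinations(pool, k):
            result = objective(combo)
            score = result[0] if isinstance(result, tuple) else float(result)
            if score > best_score:
                best_score = score
                best_subset = combo
        selected[sub] = best_subset
        diagnostics[sub] = {"score": best_score, "n_evaluated": count}
    return SelectionResult("exhaustive", selected, diagnostics)
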