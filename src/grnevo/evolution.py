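"""Evolutionary simulators: truncation selection (ESh) and stochastic
steady-state selection (ESr).

Both simulators share the same reproduction scheme: each generation the
selected survivors are preserved unchanged and each contributes one copy
subjected to a single-edge-rewiring point mutation.  They differ only in how
survivors are chosen:

* ESh ("high fitness"): strict truncation - the ``n_keep`` highest-fitness
  members survive.  Max fitness is therefore non-decreasing, and short runs
  (150 generations by default) model the transient phase of adaptation.
  Tracing parent links from the best final member back to generation 0
  yields a single evolutionary lineage.

* ESr ("randomness in selection"): each member is scored P = exp(beta f) * r
  with r uniform on [0, 1], and the ``n_keep`` largest P survive.  The
  "evolutionary temperature" beta (0.4 by default) tunes selection strength;
  the population reaches a statistical steady state whose samples probe
  evolution free of transient history.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .archive import GenotypeArchive
from .model import (Genotype, ModelParams, _rewire_inplace, as_generator)
from .fixtures import random_genotype

__all__ = [
    "EvolutionConfig", "Population", "EvolutionHistory",
    "esh_run", "trace_lineage", "esr_select", "esr_run",
    "steady_state_check",
]


@dataclass
class EvolutionConfig:
    """Shared configuration of both simulators.

    ``pop_size`` must equal ``2 * n_keep`` (survivors plus one mutated copy
    each), matching the 1000/500 scheme.  ``n_genes``/``k_edges`` shape the
    random initial population.
    """

    pop_size: int = 1000
    n_keep: int = 500
    n_generations: int = 150
    beta: float = 0.4
    sample_every: int = 100
    burn_in: int | None = None          # default 10 * sample_every
    n_genes: int = 40
    k_edges: int = 120
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_keep > self.pop_size:
            raise ValueError("n_keep must be <= pop_size")
        if self.pop_size != 2 * self.n_keep:
            raise ValueError("pop_size must equal 2 * n_keep")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    @property
    def effective_burn_in(self) -> int:
        return 10 * self.sample_every if self.burn_in is None else self.burn_in


@dataclass
class Population:
    """One generation: stacked regulation matrices, fitness, parent links.

    ``parents[i]`` is the member's index in the previous generation (its own
    former index for preserved survivors, the survivor's former index for
    mutants; -1 in generation 0).
    """

    matrices: np.ndarray        # (P, n, n) int8
    fitness: np.ndarray         # (P,)
    parents: np.ndarray         # (P,) int64
    generation: int

    @property
    def size(self) -> int:
        return self.matrices.shape[0]


class EvolutionHistory(list):
    """Generation-indexed list of :class:`Population` records."""

    def max_fitness_trajectory(self) -> np.ndarray:
        return np.array([pop.fitness.max() for pop in self])


def _eval_population(mats: np.ndarray, params: ModelParams,
                     input_gene: int, output_gene: int) -> np.ndarray:
    p, n, _ = mats.shape
    stack = mats.reshape(p, n * n).astype(np.float64)
    return _kernels.fitness_many(stack, n, input_gene, output_gene,
                                 params.alpha, params.mu,
                                 params.steady_tol, params.max_steps)


def _initial_population(cfg: EvolutionConfig, params: ModelParams,
                        rng: np.random.Generator) -> Population:
    mats = np.stack([
        random_genotype(cfg.n_genes, cfg.k_edges, rng).regulation
        for _ in range(cfg.pop_size)])
    fit = _eval_population(mats, params, 0, 1)
    return Population(mats, fit, np.full(cfg.pop_size, -1, dtype=np.int64), 0)


def _next_generation(pop: Population, survivors: np.ndarray,
                     params: ModelParams, rng: np.random.Generator,
                     mutate: bool = True) -> Population:
    """Survivors preserved unchanged followed by one mutated copy of each."""
    kept = pop.matrices[survivors]
    mutants = kept.copy()
    if mutate:
        for m in mutants:
            _rewire_inplace(m, rng)
    mats = np.concatenate([kept, mutants])
    fit = np.concatenate([
        pop.fitness[survivors],
        _eval_population(mutants, params, 0, 1) if mutate
        else pop.fitness[survivors]])
    parents = np.concatenate([survivors, survivors]).astype(np.int64)
    return Population(mats, fit, parents, pop.generation + 1)


def _truncation_select(fitness: np.ndarray, n_keep: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Indices of the n_keep fittest, ties broken uniformly at random."""
    order = np.lexsort((rng.random(fitness.size), -fitness))
    return order[:n_keep]


def esh_run(cfg: EvolutionConfig, params: ModelParams = ModelParams(),
            rng: np.random.Generator | None = None,
            mutate: bool = True) -> EvolutionHistory:
    """Transient evolution under truncation selection.

    Returns the full generation history (``n_generations + 1`` populations,
    generation 0 being the random initial set) with parent links for
    lineage tracing.
    """
    rng = as_generator(cfg.seed if rng is None else rng)
    history = EvolutionHistory()
    pop = _initial_population(cfg, params, rng)
    history.append(pop)
    for _ in range(cfg.n_generations):
        survivors = _truncation_select(pop.fitness, cfg.n_keep, rng)
        pop = _next_generation(pop, survivors, params, rng, mutate)
        history.append(pop)
    return history


def trace_lineage(history: EvolutionHistory) -> list[Genotype]:
    """Ancestral chain of the best member of the final generation.

    Returns one genotype per generation, oldest first; consecutive members
    differ by at most one rewiring.
    """
    if not history:
        raise ValueError("empty history")
    idx = int(np.argmax(history[-1].fitness))
    chain = []
    for pop in reversed(history):
        m = pop.matrices[idx]
        chain.append(Genotype(m.shape[0], m.copy()))
        idx = int(pop.parents[idx])
        if idx < 0 and pop.generation != 0:
            raise ValueError(f"broken parent link at generation {pop.generation}")
    return chain[::-1]


def esr_select(fitness: np.ndarray, n_keep: int, beta: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stochastic selection: keep the n_keep largest P = exp(beta f) * r."""
    fitness = np.asarray(fitness, dtype=np.float64)
    if fitness.size == 0:
        raise ValueError("empty population")
    # rank on log P = beta f + log r: same order as P, immune to overflow
    # at large beta
    with np.errstate(divide="ignore"):
        log_p = beta * fitness + np.log(rng.random(fitness.size))
    return np.argsort(-log_p)[:n_keep]


def steady_state_check(archive: GenotypeArchive) -> float:
    """Kolmogorov-Smirnov p-value comparing the fitness distributions of the
    first and second halves of an ESr archive.

    A small p-value indicates the archive still contains transient drift and
    the burn-in should be extended.
    """
    from scipy import stats

    f = archive.fitness_array
    if f.size < 4:
        raise ValueError("archive too small for a steady-state check")
    half = f.size // 2
    return float(stats.ks_2samp(f[:half], f[half:]).pvalue)


def esr_run(cfg: EvolutionConfig, params: ModelParams = ModelParams(),
            rng: np.random.Generator | None = None) -> GenotypeArchive:
    """Steady-state evolution under stochastic selection.

    After ``burn_in`` generations (10 * sample_every by default), the
    ``n_keep`` preserved members are recorded every ``sample_every``
    generations.  Samples are tagged with fitness and generation.
    """
    rng = as_generator(cfg.seed if rng is None else rng)
    archive = GenotypeArchive(0, 1, seed=cfg.seed)
    pop = _initial_population(cfg, params, rng)
    for gen in range(1, cfg.n_generations + 1):
        survivors = esr_select(pop.fitness, cfg.n_keep, cfg.beta, rng)
        pop = _next_generation(pop, survivors, params, rng)
        if gen > cfg.effective_burn_in and gen % cfg.sample_every == 0:
            for i in range(cfg.n_keep):
                archive.add(pop.matrices[i], pop.fitness[i], generation=gen)
    return archive
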