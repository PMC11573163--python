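"""Structural analyses: the ++++ motif, activation-edge counts, stochastic
network reduction, and categorisation of essential-edge cut outcomes.

The ++++ motif is the four-edge all-activation core observed in mutationally
robust one-way switches: auto-activation loops on the input and output genes
plus mutual activation between them.  Network reduction strips a
high-fitness genotype down to a minimal functional core by repeated random
edge deletion subject to keeping fitness above a threshold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .model import Genotype, ModelParams, as_generator, fitness, fitness_of_matrix
from .phenotype import (INTRINSIC_ONE_WAY, MONOSTABLE, TOGGLE,
                        classify_extended)
from .robustness import cut_edge, essential_edges

__all__ = [
    "MotifReport", "ReducedNetwork",
    "motif_report", "reduce_network", "cut_outcome_census",
]

#: census categories for essential-edge cut outcomes
CENSUS_CATEGORIES = (INTRINSIC_ONE_WAY, TOGGLE, MONOSTABLE)


@dataclass(frozen=True)
class MotifReport:
    has_full_motif: bool
    present_motif_edges: tuple[str, ...]
    n_activation_edges: int


@dataclass
class ReducedNetwork:
    genotype: Genotype
    n_edges: int
    fitness: float
    deletion_trace: list[tuple[int, int]]   # (source, target), deletion order


def motif_report(g: Genotype) -> MotifReport:
    """Check the four ++++ motif positions and count all +1 edges.

    Pure structure - no dynamics - and invariant under relabelling of
    non-terminal genes.
    """
    i, o = g.input_gene, g.output_gene
    positions = {
        "input_auto": (i, i),
        "output_auto": (o, o),
        "input_to_output": (o, i),   # row = target, col = source
        "output_to_input": (i, o),
    }
    present = tuple(name for name, (r, c) in positions.items()
                    if g.regulation[r, c] == 1)
    return MotifReport(
        has_full_motif=len(present) == 4,
        present_motif_edges=present,
        n_activation_edges=int((g.regulation == 1).sum()))


def _one_pass(mat: np.ndarray, g: Genotype, params: ModelParams,
              f_threshold: float, rng: np.random.Generator,
              ) -> tuple[np.ndarray, list[int]]:
    """Greedy stochastic descent: delete random edges while fitness stays
    above the threshold; the first rejected deletion ends the pass."""
    trace = []
    while True:
        cells = np.flatnonzero(mat)
        if cells.size == 0:
            return mat, trace
        cell = int(cells[rng.integers(cells.size)])
        old = mat.reshape(-1)[cell]
        mat.reshape(-1)[cell] = 0
        if fitness_of_matrix(mat, g.input_gene, g.output_gene, params) > f_threshold:
            trace.append(cell)
        else:
            mat.reshape(-1)[cell] = old
            return mat, trace


def reduce_network(g: Genotype, params: ModelParams = ModelParams(),
                   f_threshold: float = 0.8, n_restarts: int = 1000,
                   rng: np.random.Generator | None = None,
                   seed: int | None = None) -> ReducedNetwork:
    """Strip a genotype to a minimal core keeping fitness above the threshold.

    Runs ``n_restarts`` independent random deletion passes from the current
    network and keeps the fewest-edge result; the whole procedure is then
    re-applied to that result until a full round yields no further
    reduction.  Requires the baseline fitness to exceed the threshold.
    """
    base = fitness(g, params).f
    if base <= f_threshold:
        raise ValueError(
            f"baseline fitness {base:.3f} does not exceed threshold {f_threshold}")
    rng = as_generator(seed if rng is None else rng)
    n = g.n_genes
    best = g.regulation.copy()
    best_trace: list[int] = []
    while True:
        round_best = None
        round_trace = None
        for _ in range(n_restarts):
            mat, trace = _one_pass(best.copy(), g, params, f_threshold, rng)
            if round_best is None or np.count_nonzero(mat) < np.count_nonzero(round_best):
                round_best, round_trace = mat, trace
        if np.count_nonzero(round_best) >= np.count_nonzero(best):
            break
        best = round_best
        best_trace.extend(round_trace)
    reduced = Genotype(n, best, g.input_gene, g.output_gene)
    return ReducedNetwork(
        genotype=reduced,
        n_edges=reduced.n_edges,
        fitness=fitness(reduced, params).f,
        deletion_trace=[(c % n, c // n) for c in best_trace])


def cut_outcome_census(g: Genotype, params: ModelParams = ModelParams(),
                       threshold: float = 0.5,
                       lo: float = -10.0, hi: float = 10.0,
                       step_size: float = 0.01):
    """Classify the genotype obtained by cutting each essential edge.

    Each cut genotype is swept over the extended input range and assigned
    one of three categories: intrinsically one-way, toggle (hysteresis whose
    loop closes in range), or monostable.  Returns ``(counts, per_edge)``
    where counts is a Counter over categories (summing to N_ee) and
    per_edge maps (source, target) to its category.
    """
    profile = essential_edges(g, params, threshold)
    counts: Counter = Counter({c: 0 for c in CENSUS_CATEGORIES})
    per_edge = {}
    for pos in profile.essential_edges:
        call = classify_extended(cut_edge(g, pos), params,
                                 lo=lo, hi=hi, step_size=step_size)
        if call.label == MONOSTABLE:
            cat = MONOSTABLE
        elif call.refined_label == INTRINSIC_ONE_WAY:
            cat = INTRINSIC_ONE_WAY
        else:
            cat = TOGGLE
        counts[cat] += 1
        per_edge[pos] = cat
    return counts, per_edge
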