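"""Mutational-robustness metrics: essential edges and the lethal-mutation ratio.

An edge is *essential* when the genotype's fitness after cutting that single
edge falls below 0.5 (a threshold on the post-cut fitness itself, not on the
drop relative to baseline; meaningful for genotypes with baseline fitness
well above 0.5).  The count of essential edges N_ee inversely proxies
mutational robustness.

Because evolution mutates by rewiring rather than by cutting, the
*lethal-mutation ratio* r_l complements N_ee: the fraction of random
single-edge rewirings that push fitness below the same threshold.  The two
are strongly positively correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (Genotype, ModelParams, _rewire_inplace, as_generator,
                    fitness, fitness_of_matrix)

__all__ = [
    "EssentialEdgeProfile", "LethalRatio",
    "cut_edge", "essential_edges", "lethal_ratio",
]


@dataclass
class EssentialEdgeProfile:
    """Outcome of all single-edge cuts of one genotype.

    ``edges`` lists all (source, target, sign) edges in matrix order;
    ``per_edge_fitness[i]`` is the fitness after cutting ``edges[i]`` alone.
    """

    baseline_fitness: float
    edges: list[tuple[int, int, int]]
    per_edge_fitness: np.ndarray
    threshold: float

    @property
    def essential_mask(self) -> np.ndarray:
        return self.per_edge_fitness < self.threshold

    @property
    def essential_edges(self) -> list[tuple[int, int]]:
        return [(s, t) for (s, t, _), e in zip(self.edges, self.essential_mask)
                if e]

    @property
    def n_essential(self) -> int:
        return int(self.essential_mask.sum())

    def to_frame(self):
        import pandas as pd
        src, tgt, sign = zip(*self.edges) if self.edges else ((), (), ())
        return pd.DataFrame({
            "source": src, "target": tgt, "sign": sign,
            "post_cut_fitness": self.per_edge_fitness,
            "essential": self.essential_mask,
        })


@dataclass(frozen=True)
class LethalRatio:
    """Fraction of random rewirings dropping fitness below the threshold."""

    r_l: float
    n_trials: int
    threshold: float
    seed: int | None = None


def cut_edge(g: Genotype, position: tuple[int, int]) -> Genotype:
    """Copy of ``g`` with the edge source->target removed (K - 1 edges left)."""
    src, tgt = position
    if g.regulation[tgt, src] == 0:
        raise ValueError(f"no edge at position source={src}, target={tgt}")
    out = g.copy()
    out.regulation[tgt, src] = 0
    return out


def essential_edges(g: Genotype, params: ModelParams = ModelParams(),
                    threshold: float = 0.5) -> EssentialEdgeProfile:
    """Try all K single-edge cuts; an edge is essential iff the cut genotype's
    fitness is below ``threshold``.  Deterministic."""
    baseline = fitness(g, params).f
    edges = g.edges()
    post = np.empty(len(edges))
    mat = g.regulation.copy()
    for i, (src, tgt, sign) in enumerate(edges):
        mat[tgt, src] = 0
        post[i] = fitness_of_matrix(mat, g.input_gene, g.output_gene, params)
        mat[tgt, src] = sign
    return EssentialEdgeProfile(baseline, edges, post, threshold)


def lethal_ratio(g: Genotype, params: ModelParams = ModelParams(),
                 n_trials: int = 1000, threshold: float = 0.5,
                 rng: np.random.Generator | None = None,
                 seed: int | None = None) -> LethalRatio:
    """Estimate r_l from ``n_trials`` independent single-edge rewirings of g.

    Each trial rewires the original genotype once (mutants are not chained)
    and evaluates the mutant's fitness with the same steady-state protocol
    as the baseline.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = as_generator(seed if rng is None else rng)
    lethal = 0
    for _ in range(n_trials):
        mat = g.regulation.copy()
        _rewire_inplace(mat, rng)
        if fitness_of_matrix(mat, g.input_gene, g.output_gene, params) < threshold:
            lethal += 1
    return LethalRatio(lethal / n_trials, n_trials, threshold, seed)
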