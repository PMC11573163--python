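"""Programmatic genotype generators with known properties.

These cover every structural case the rest of the toolkit needs: random
genotypes (the initial populations of the evolutionary simulators), random
acyclic genotypes (guaranteed monostable), a serial activation chain (every
edge on the single input->output path), the two-gene all-activation motif,
a core plus fitness-inert appendage edges, and the exhaustive enumeration of
a small genotype space (the brute-force oracle for the samplers).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model import Genotype, as_generator

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "random_genotype",
    "acyclic_random_genotype",
    "serial_chain",
    "two_gene_pppp",
    "with_appendage",
    "enumeration_space",
]

KINDS = ("random", "acyclic_random", "serial_chain", "two_gene_pppp",
         "appendage", "enumeration_space")


@dataclass
class FixtureSpec:
    kind: str
    n_genes: int = 2
    k_edges: int = 2
    seed: int | None = None
    core: Genotype | None = None      # appendage only
    n_inert_edges: int = 0            # appendage only

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"choose from {KINDS}")


def random_genotype(n_genes: int, k_edges: int,
                    rng: np.random.Generator,
                    input_gene: int = 0, output_gene: int = 1) -> Genotype:
    """K distinct cells chosen uniformly, signs uniform +/-1."""
    ncells = n_genes * n_genes
    if not 1 <= k_edges <= ncells:
        raise ValueError(f"k_edges={k_edges} infeasible for {n_genes} genes")
    cells = rng.choice(ncells, size=k_edges, replace=False)
    mat = np.zeros(ncells, dtype=np.int8)
    mat[cells] = rng.choice([-1, 1], size=k_edges)
    return Genotype(n_genes, mat.reshape(n_genes, n_genes),
                    input_gene, output_gene)


def acyclic_random_genotype(n_genes: int, k_edges: int,
                            rng: np.random.Generator) -> Genotype:
    """Random DAG genotype: edges respect a random topological order.

    No self-loops and no directed feedback, so the dynamics always converge
    and the genotype is monostable.
    """
    max_edges = n_genes * (n_genes - 1) // 2
    if not 1 <= k_edges <= max_edges:
        raise ValueError(
            f"k_edges={k_edges} infeasible for an acyclic {n_genes}-gene "
            f"genotype (max {max_edges})")
    order = rng.permutation(n_genes)
    pairs = [(order[a], order[b])          # source earlier in the order
             for a in range(n_genes) for b in range(a + 1, n_genes)]
    chosen = rng.choice(len(pairs), size=k_edges, replace=False)
    mat = np.zeros((n_genes, n_genes), dtype=np.int8)
    for idx in chosen:
        src, tgt = pairs[idx]
        mat[tgt, src] = rng.choice([-1, 1])
    return Genotype(n_genes, mat)


def serial_chain(n_genes: int) -> Genotype:
    """All-activation chain input -> g2 -> ... -> output (gene 1).

    Every edge lies on the unique input->output path, so cutting any edge
    drops the fitness to zero.
    """
    if n_genes < 2:
        raise ValueError("serial chain needs at least 2 genes")
    mat = np.zeros((n_genes, n_genes), dtype=np.int8)
    path = [0] + list(range(2, n_genes)) + [1]
    for src, tgt in zip(path[:-1], path[1:]):
        mat[tgt, src] = 1
    return Genotype(n_genes, mat)


def two_gene_pppp() -> Genotype:
    """The four-edge all-activation (++++) motif as a complete 2-gene genotype:
    auto-activation of input and output plus mutual activation."""
    return Genotype(2, np.ones((2, 2), dtype=np.int8))


def with_appendage(core: Genotype, n_extra_genes: int, n_inert_edges: int,
                   rng: np.random.Generator) -> Genotype:
    """Embed ``core`` and add edges among fresh genes only.

    The appendage genes have no edges to or from the core, so they can
    neither reach nor be reached from the output: the added edges are
    provably fitness-neutral.
    """
    if n_extra_genes < 1:
        raise ValueError("appendage needs at least one extra gene")
    if n_inert_edges > n_extra_genes * n_extra_genes:
        raise ValueError("too many inert edges for the appendage size")
    n = core.n_genes + n_extra_genes
    mat = np.zeros((n, n), dtype=np.int8)
    mat[:core.n_genes, :core.n_genes] = core.regulation
    cells = rng.choice(n_extra_genes * n_extra_genes, size=n_inert_edges,
                       replace=False)
    for c in cells:
        i, j = divmod(int(c), n_extra_genes)
        mat[core.n_genes + i, core.n_genes + j] = rng.choice([-1, 1])
    return Genotype(n, mat, core.input_gene, core.output_gene)


def enumeration_space(n_genes: int, k_edges: int) -> list[Genotype]:
    """Every genotype with exactly ``k_edges`` edges on ``n_genes`` genes.

    There are C(n^2, K) * 2^K of them; e.g. 24 for (2, 2).  Used as the
    exact reference for the sampler tests.
    """
    ncells = n_genes * n_genes
    count = 1
    for i in range(k_edges):
        count = count * (ncells - i) // (i + 1)
    count *= 2 ** k_edges
    if count > 200_000:
        raise ValueError(f"enumeration space too large ({count} genotypes)")
    out = []
    for cells in itertools.combinations(range(ncells), k_edges):
        for signs in itertools.product((-1, 1), repeat=k_edges):
            mat = np.zeros(ncells, dtype=np.int8)
            mat[list(cells)] = signs
            out.append(Genotype(n_genes, mat.reshape(n_genes, n_genes)))
    return out


def make_fixture(spec: FixtureSpec, rng: np.random.Generator | None = None):
    """Dispatch on ``spec.kind``; returns a Genotype or a list of them."""
    rng = as_generator(spec.seed if rng is None else rng)
    if spec.kind == "random":
        return random_genotype(spec.n_genes, spec.k_edges, rng)
    if spec.kind == "acyclic_random":
        return acyclic_random_genotype(spec.n_genes, spec.k_edges, rng)
    if spec.kind == "serial_chain":
        return serial_chain(spec.n_genes)
    if spec.kind == "two_gene_pppp":
        return two_gene_pppp()
    if spec.kind == "appendage":
        if spec.core is None:
            raise ValueError("appendage fixture needs a core genotype")
        n_extra = spec.n_genes - spec.core.n_genes
        return with_appendage(spec.core, n_extra, spec.n_inert_edges, rng)
    if spec.kind == "enumeration_space":
        return enumeration_space(spec.n_genes, spec.k_edges)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
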