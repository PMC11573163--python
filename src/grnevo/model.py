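"""Discrete-time GRN model: genotype, expression dynamics, fitness, mutation.

A genotype is a signed directed graph on ``n_genes`` genes, stored as an
``n x n`` matrix ``J`` with entries in {-1, 0, +1}; ``J[i, j]`` is the
regulation of gene ``i`` by gene ``j`` (+1 activation, -1 repression).
Self-regulation (diagonal entries) is allowed.  Gene ``input_gene`` receives
an external input ``I`` added to its regulatory sum; gene ``output_gene``
is read out.

The expression dynamics are synchronous:

    x_i(t+1) = R(I * [i == input] + sum_j J[i, j] x_j(t)),
    R(y) = 1 / (1 + exp(-alpha * (y - mu))).

With the defaults alpha = 2.0 and mu = 0.424 an unregulated gene settles at
R(0) ~= 0.3, the "spontaneous" expression level used to initialise all runs.

Fitness measures switch-like response with history: run to steady state at
I = 0 from the spontaneous state, then, keeping the expression levels, run to
steady state at I = 1; ``f = max(x_out(1) - x_out(0), 0)``.

The unit mutation shared by the samplers and the evolutionary simulators is a
single-edge rewiring: cut one uniformly chosen edge, then place a new edge of
uniform random sign on a uniformly chosen empty cell (the just-cut cell is
eligible again, so the proposal is symmetric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels

__all__ = [
    "ModelParams",
    "Genotype",
    "ExpressionState",
    "FitnessValue",
    "response",
    "spontaneous_level",
    "step",
    "run_to_steady",
    "fitness",
    "rewire",
]


@dataclass(frozen=True)
class ModelParams:
    """Response-function and steady-state parameters.

    alpha
        Steepness of the sigmoidal response (> 0).
    mu
        Response threshold; ``R(mu) = 1/2``.
    steady_tol
        Convergence criterion: max-abs change of expression between
        consecutive steps.  Kept well below the 1e-6 threshold used by the
        phenotype classifier so classification is tolerance-robust.
    max_steps
        Iteration cap; on hitting it the trajectory is averaged over the
        final window and flagged as non-convergent (limit cycles).
    """

    alpha: float = 2.0
    mu: float = 0.424
    steady_tol: float = 1e-9
    max_steps: int = 10_000

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.steady_tol <= 0:
            raise ValueError("steady_tol must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass
class Genotype:
    """Signed regulation matrix with designated input and output genes."""

    n_genes: int
    regulation: np.ndarray
    input_gene: int = 0
    output_gene: int = 1

    def __post_init__(self) -> None:
        self.regulation = np.asarray(self.regulation, dtype=np.int8)
        if self.regulation.shape != (self.n_genes, self.n_genes):
            raise ValueError(
                f"regulation matrix has shape {self.regulation.shape}, "
                f"expected ({self.n_genes}, {self.n_genes})")
        bad = np.setdiff1d(np.unique(self.regulation), [-1, 0, 1])
        if bad.size:
            raise ValueError(f"regulation entries must be -1, 0 or +1; got {bad}")
        for name in ("input_gene", "output_gene"):
            idx = getattr(self, name)
            if not (0 <= idx < self.n_genes):
                raise ValueError(f"{name}={idx} out of range for {self.n_genes} genes")
        if self.input_gene == self.output_gene:
            raise ValueError("input_gene and output_gene must differ")

    @property
    def n_edges(self) -> int:
        """Current edge count K (number of nonzero matrix entries)."""
        return int(np.count_nonzero(self.regulation))

    def copy(self) -> "Genotype":
        return Genotype(self.n_genes, self.regulation.copy(),
                        self.input_gene, self.output_gene)

    def edges(self) -> list[tuple[int, int, int]]:
        """Edge list as (source, target, sign) with J[target, source] = sign."""
        tgt, src = np.nonzero(self.regulation)
        return [(int(s), int(t), int(self.regulation[t, s]))
                for t, s in zip(tgt, src)]

    def key(self) -> bytes:
        """Hashable identity of the regulation matrix (terminals excluded)."""
        return self.regulation.tobytes()

    def __eq__(self, other) -> bool:
        return (isinstance(other, Genotype)
                and self.n_genes == other.n_genes
                and self.input_gene == other.input_gene
                and self.output_gene == other.output_gene
                and np.array_equal(self.regulation, other.regulation))

    def _lin(self) -> np.ndarray:
        return self.regulation.astype(np.float64).ravel()


@dataclass
class ExpressionState:
    """Per-gene expression levels in [0, 1] plus the current external input."""

    levels: np.ndarray
    input_value: float = 0.0

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.float64)


@dataclass(frozen=True)
class FitnessValue:
    """Fitness f = max(x_out(1) - x_out(0), 0) and its two steady outputs."""

    f: float
    x_out_0: float
    x_out_1: float
    converged_0: bool = True
    converged_1: bool = True

    @property
    def converged(self) -> bool:
        return self.converged_0 and self.converged_1


def response(y, params: ModelParams = ModelParams()):
    """Sigmoidal response R(y) = 1 / (1 + exp(-alpha (y - mu))).

    Accepts scalars or arrays; the exponent is saturated at +/-700 so the
    result is always a finite number in (0, 1) (up to floating underflow).
    """
    y = np.asarray(y, dtype=np.float64)
    z = np.clip(-params.alpha * (y - params.mu), -700.0, 700.0)
    out = 1.0 / (1.0 + np.exp(z))
    return float(out) if out.ndim == 0 else out


def spontaneous_level(params: ModelParams = ModelParams()) -> float:
    """Fixed expression of an unregulated gene with no input: R(0).

    With the default parameters this is 0.29986..., i.e. ~0.3.  All dynamics
    are initialised at this exact value (the true fixed point), not at the
    rounded 0.3.
    """
    return response(0.0, params)


def spontaneous_state(g: Genotype, params: ModelParams = ModelParams(),
                      input_value: float = 0.0) -> ExpressionState:
    """All genes at the spontaneous level."""
    return ExpressionState(np.full(g.n_genes, spontaneous_level(params)),
                           input_value)


def step(state: ExpressionState, g: Genotype,
         params: ModelParams = ModelParams()) -> ExpressionState:
    """One synchronous update of all genes."""
    if state.levels.shape[0] != g.n_genes:
        raise ValueError(
            f"state has {state.levels.shape[0]} levels for {g.n_genes} genes")
    drive = g.regulation.astype(np.float64) @ state.levels
    drive[g.input_gene] += state.input_value
    return ExpressionState(response(drive, params), state.input_value)


def run_to_steady(g: Genotype, input_value: float,
                  init: ExpressionState | None = None,
                  params: ModelParams = ModelParams(),
                  ) -> tuple[ExpressionState, bool]:
    """Iterate the dynamics at fixed input until (near) stationarity.

    Returns the steady state and a convergence flag.  If ``max_steps`` is
    reached (e.g. a limit cycle), the element-wise mean over the final
    100-step window is returned with ``converged=False``; a period-2 cycle is
    detected early and averaged identically.
    """
    if init is None:
        init = spontaneous_state(g, params, input_value)
    if init.levels.shape[0] != g.n_genes:
        raise ValueError(
            f"init state has {init.levels.shape[0]} levels for {g.n_genes} genes")
    x, conv = _kernels.steady_state(
        g._lin(), g.n_genes, float(input_value),
        np.asarray(init.levels, dtype=np.float64),
        g.input_gene, params.alpha, params.mu,
        params.steady_tol, params.max_steps)
    return ExpressionState(x, float(input_value)), bool(conv)


def fitness(g: Genotype, params: ModelParams = ModelParams()) -> FitnessValue:
    """History-dependent fitness of a genotype.

    Phase 1 starts every gene at the spontaneous level with I = 0 and runs to
    steady state; phase 2 switches to I = 1 without resetting expression and
    runs again.  Non-convergent phases are flagged and evaluated from the
    averaged surrogate state.
    """
    f, x0, x1, c0, c1 = _kernels.fitness_eval(
        g._lin(), g.n_genes, g.input_gene, g.output_gene,
        params.alpha, params.mu, params.steady_tol, params.max_steps)
    return FitnessValue(float(f), float(x0), float(x1), bool(c0), bool(c1))


def fitness_of_matrix(mat: np.ndarray, input_gene: int = 0,
                      output_gene: int = 1,
                      params: ModelParams = ModelParams()) -> float:
    """Fitness from a raw regulation matrix (fast path, no Genotype checks)."""
    f, _, _, _, _ = _kernels.fitness_eval(
        np.asarray(mat, dtype=np.float64).ravel(), mat.shape[0],
        input_gene, output_gene, params.alpha, params.mu,
        params.steady_tol, params.max_steps)
    return float(f)


def _rewire_inplace(mat: np.ndarray, rng: np.random.Generator) -> tuple[int, int]:
    """Single-edge rewiring of a flat-indexable int8 matrix, in place.

    Returns the (cut_cell, new_cell) linear indices.  The refill cell is
    uniform over all cells empty *after* the cut (the cut cell included),
    with a uniform +/-1 sign.
    """
    flat = mat.reshape(-1)
    nonzero = np.flatnonzero(flat)
    if nonzero.size == 0:
        raise ValueError("cannot rewire a genotype with no edges")
    if nonzero.size == flat.size:
        raise ValueError("cannot rewire a fully connected genotype")
    cut = int(nonzero[rng.integers(nonzero.size)])
    flat[cut] = 0
    # rejection sampling: uniform over currently-empty cells
    while True:
        cell = int(rng.integers(flat.size))
        if flat[cell] == 0:
            break
    flat[cell] = 1 if rng.random() < 0.5 else -1
    return cut, cell


def rewire(g: Genotype, rng: np.random.Generator) -> Genotype:
    """Mutate by single-edge rewiring; returns a new genotype, K preserved."""
    out = g.copy()
    _rewire_inplace(out.regulation, rng)
    return out


def as_generator(rng_or_seed) -> np.random.Generator:
    """Coerce a seed / Generator / None into a numpy Generator."""
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def kernel_seed(rng: np.random.Generator) -> int:
    """Derive a 31-bit seed for a numba kernel from a Generator."""
    return int(rng.integers(1, 2**31 - 1))
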