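"""Quasi-static input sweeps and three-way phenotype classification.

The phenotype of a genotype is read off its hysteresis behaviour under a
quasi-static input sweep with state continuation: raise I from 0 to 1 in
steps of 0.005, running to steady state at each value from the previous
steady state, then lower it back along the same grid starting from the I = 1
steady state.

* monostable      - up and down trajectories coincide everywhere (< 1e-6);
* toggle switch   - they differ over an intermediate range but rejoin at I=0
                    (a hysteresis loop with both saddle-node points in range);
* one-way switch  - the output does not return to its initial value at I=0
                    (only one saddle-node bifurcation in range; the
                    transition is irreversible).

Over an extended input range (default I in [-10, 10]) a one-way switch is
refined into "intrinsically one-way" (the loop never closes: a single
saddle-node point) or an off-range toggle (the lower closure sits at I < 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import ExpressionState, Genotype, ModelParams, spontaneous_state

__all__ = [
    "MONOSTABLE", "TOGGLE", "ONE_WAY",
    "INTRINSIC_ONE_WAY", "OFF_RANGE_TOGGLE",
    "SweepTrajectory", "PhenotypeCall",
    "sweep", "classify", "classify_extended",
]

MONOSTABLE = "monostable"
TOGGLE = "toggle_switch"
ONE_WAY = "one_way_switch"
INTRINSIC_ONE_WAY = "intrinsically_one_way"
OFF_RANGE_TOGGLE = "off_range_toggle"


@dataclass
class SweepTrajectory:
    """Output-gene levels recorded along one sweep direction."""

    input_grid: np.ndarray
    outputs: np.ndarray
    converged_flags: np.ndarray
    direction: str                      # "upward" | "downward"
    final_state: ExpressionState | None = None

    def __post_init__(self) -> None:
        if len(self.input_grid) != len(self.outputs):
            raise ValueError("grid and outputs must have equal length")

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "direction": self.direction,
            "input": self.input_grid,
            "output": self.outputs,
            "converged": self.converged_flags,
        })


@dataclass
class PhenotypeCall:
    label: str
    max_gap: float
    endpoint_gap: float
    refined_label: str | None = None
    jump_points: list = field(default_factory=list)
    all_converged: bool = True


def _grid(start: float, end: float, step_size: float) -> np.ndarray:
    """Inclusive-endpoint grid from start to end (either direction)."""
    n = int(round(abs(end - start) / step_size)) + 1
    return np.linspace(start, end, n)


def sweep(g: Genotype, start: float, end: float, step_size: float,
          params: ModelParams = ModelParams(),
          init: ExpressionState | None = None) -> SweepTrajectory:
    """Quasi-static sweep of the input with state continuation.

    The first grid point is equilibrated from ``init`` (spontaneous levels
    by default); each subsequent point restarts from the previous steady
    state.  Direction is inferred from the sign of ``end - start``.
    """
    if step_size <= 0:
        raise ValueError("step_size must be positive")
    if start == end:
        raise ValueError("start and end must differ")
    grid = _grid(start, end, step_size)
    if init is None:
        init = spontaneous_state(g, params, grid[0])
    outs, conv, final = _kernels.sweep_outputs(
        g._lin(), g.n_genes, grid,
        np.asarray(init.levels, dtype=np.float64),
        g.input_gene, g.output_gene,
        params.alpha, params.mu, params.steady_tol, params.max_steps)
    return SweepTrajectory(grid, outs, conv,
                           "upward" if end > start else "downward",
                           ExpressionState(final, grid[-1]))


def _up_down(g: Genotype, lo: float, hi: float, step_size: float,
             params: ModelParams) -> tuple[SweepTrajectory, SweepTrajectory]:
    up = sweep(g, lo, hi, step_size, params)
    down = sweep(g, hi, lo, step_size, params, init=up.final_state)
    return up, down


def _call(up: SweepTrajectory, down: SweepTrajectory,
          eps: float) -> tuple[str, float, float]:
    diffs = np.abs(up.outputs - down.outputs[::-1])
    max_gap = float(diffs.max())
    endpoint_gap = float(diffs[0])
    if max_gap < eps:
        label = MONOSTABLE
    elif endpoint_gap > eps:
        # irreversibility at the low endpoint takes precedence over any
        # intermediate hysteresis
        label = ONE_WAY
    else:
        label = TOGGLE
    return label, max_gap, endpoint_gap


def classify(g: Genotype, params: ModelParams = ModelParams(),
             eps: float = 1e-6, step_size: float = 0.005) -> PhenotypeCall:
    """Three-way phenotype call from up/down sweeps over I in [0, 1].

    Oscillatory genotypes are classified from the averaged surrogate states
    and flagged via ``all_converged=False``.
    """
    up, down = _up_down(g, 0.0, 1.0, step_size, params)
    label, max_gap, endpoint_gap = _call(up, down, eps)
    return PhenotypeCall(
        label, max_gap, endpoint_gap,
        all_converged=bool(up.converged_flags.all()
                           and down.converged_flags.all()))


def _jumps(traj: SweepTrajectory, jump_eps: float) -> list[float]:
    d = np.abs(np.diff(traj.outputs))
    return [float(traj.input_grid[k + 1]) for k in np.nonzero(d > jump_eps)[0]]


def classify_extended(g: Genotype, params: ModelParams = ModelParams(),
                      lo: float = -10.0, hi: float = 10.0,
                      step_size: float = 0.01, jump_eps: float = 0.1,
                      eps: float = 1e-6) -> PhenotypeCall:
    """Phenotype call over an extended input range with saddle-node jumps.

    ``jump_points`` collects grid values where the output changes by more
    than ``jump_eps`` between adjacent grid points (either direction).  For
    any genotype showing hysteresis over the range, ``refined_label`` is
    ``intrinsically_one_way`` when the down sweep never rejoins the up
    sweep's low branch (single saddle-node point), else
    ``off_range_toggle`` (the hysteresis loop closes within the range, which
    for a genotype one-way on [0, 1] means closure at I < 0).
    """
    up, down = _up_down(g, lo, hi, step_size, params)
    label, max_gap, endpoint_gap = _call(up, down, eps)
    refined = None
    if label is not MONOSTABLE:
        refined = INTRINSIC_ONE_WAY if endpoint_gap > eps else OFF_RANGE_TOGGLE
    return PhenotypeCall(
        label, max_gap, endpoint_gap, refined_label=refined,
        jump_points=sorted(set(_jumps(up, jump_eps) + _jumps(down, jump_eps))),
        all_converged=bool(up.converged_flags.all()
                           and down.converged_flags.all()))
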