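"""Multicanonical Monte Carlo over fitness bins.

High-fitness genotypes are exponentially rare, so plain random sampling
cannot build a reference ensemble across the whole fitness range.  The
multicanonical approach walks genotype space with single-edge-rewiring
proposals and acceptance weights inversely proportional to the density of
states over 100 fitness bins, visiting all bins roughly evenly:

1. :func:`wang_landau` estimates the per-bin log density of states S(k)
   (genotypic entropy up to a constant) by penalising the current bin with a
   shrinking increment until the visit histogram is flat.
2. :func:`entropic_sampling` freezes those weights and records genotypes at a
   fixed stride; within each bin, genotypes are sampled uniformly.

A Monte Carlo step (MCS) is K elementary rewiring trials, where K is the
edge count; samples are recorded every 20 MCS by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .archive import GenotypeArchive
from .model import Genotype, ModelParams, as_generator, kernel_seed

__all__ = [
    "BinScheme", "WeightTable", "McmcConfig",
    "fitness_bin", "wang_landau", "entropic_sampling", "genotypic_entropy",
]


@dataclass(frozen=True)
class BinScheme:
    """Equal-width partition of f in [0, 1]; bin k is [k/n, (k+1)/n),
    with the last bin closed at 1."""

    n_bins: int = 100

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    def edges(self, k: int) -> tuple[float, float]:
        return k / self.n_bins, (k + 1) / self.n_bins


def fitness_bin(f: float, scheme: BinScheme = BinScheme()) -> int:
    """Bin index of a fitness value; f = 1 maps to the last bin."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"fitness {f} outside [0, 1]")
    return min(int(f * scheme.n_bins), scheme.n_bins - 1)


@dataclass
class WeightTable:
    """Per-bin log density-of-states estimate and sampler bookkeeping."""

    log_dos: np.ndarray
    histogram: np.ndarray
    visited: np.ndarray
    wl_modification: float
    scheme: BinScheme = field(default_factory=BinScheme)
    converged: bool = True

    @classmethod
    def uniform(cls, scheme: BinScheme = BinScheme()) -> "WeightTable":
        """All-equal weights with every bin marked visited: the fixed-weight
        walk degenerates to a symmetric random walk on genotype space."""
        n = scheme.n_bins
        return cls(np.zeros(n), np.zeros(n, dtype=np.int64),
                   np.ones(n, dtype=bool), 0.0, scheme)

    def to_frame(self):
        import pandas as pd
        lo = np.arange(self.scheme.n_bins) / self.scheme.n_bins
        return pd.DataFrame({
            "bin": np.arange(self.scheme.n_bins),
            "f_lo": lo,
            "f_hi": lo + 1.0 / self.scheme.n_bins,
            "log_dos": self.log_dos,
            "visits": self.histogram,
            "visited": self.visited,
        })


@dataclass
class McmcConfig:
    """Budget and schedule of one sampler run.

    ``n_mcs`` is the trial budget in Monte Carlo steps (one MCS = K rewiring
    trials unless ``trials_per_mcs`` overrides it).  The Wang-Landau schedule
    (initial increment 1.0, flatness 0.8, halving, final increment 1e-4) is
    standard practice; the method itself fixes none of these.
    """

    n_mcs: int = 100_000
    sample_interval_mcs: int = 20
    trials_per_mcs: int | None = None      # default: the genotype's K
    wl_flatness: float = 0.8
    wl_initial_increment: float = 1.0
    wl_final_increment: float = 1e-4
    flatness_check_interval: int = 5_000   # trials
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_mcs", "sample_interval_mcs", "flatness_check_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.wl_flatness <= 1:
            raise ValueError("wl_flatness must be in (0, 1]")
        if self.trials_per_mcs is not None and self.trials_per_mcs <= 0:
            raise ValueError("trials_per_mcs must be positive")

    def trials(self, g: Genotype) -> int:
        return self.trials_per_mcs if self.trials_per_mcs else g.n_edges


def wang_landau(g0: Genotype, cfg: McmcConfig,
                scheme: BinScheme = BinScheme(),
                params: ModelParams = ModelParams(),
                rng: np.random.Generator | None = None) -> WeightTable:
    """Estimate per-bin log density of states by the Wang-Landau method.

    Acceptance is min(1, exp(S(old bin) - S(new bin))); after every trial the
    current bin's S is raised by the modification factor and the histogram
    incremented.  When the histogram over visited bins is flat (min >=
    flatness * mean) the factor is halved and the histogram reset; the run
    stops when the factor drops below ``wl_final_increment`` or the ``n_mcs``
    budget is exhausted (then ``converged`` is False).
    """
    rng = as_generator(cfg.seed if rng is None else rng)
    n = scheme.n_bins
    log_dos = np.zeros(n)
    hist = np.zeros(n, dtype=np.int64)
    visited = np.zeros(n, dtype=bool)
    Jlin = g0._lin()
    max_trials = cfg.n_mcs * cfg.trials(g0)
    _, final_inc = _kernels.wang_landau_walk(
        Jlin, g0.n_genes, g0.input_gene, g0.output_gene,
        params.alpha, params.mu, params.steady_tol, params.max_steps,
        n, log_dos, hist, visited,
        cfg.wl_initial_increment, cfg.wl_flatness, cfg.wl_final_increment,
        cfg.flatness_check_interval, max_trials, kernel_seed(rng))
    log_dos[~visited] = -np.inf
    return WeightTable(log_dos, hist, visited, final_inc, scheme,
                       converged=final_inc < cfg.wl_final_increment)


def entropic_sampling(g0: Genotype, weights: WeightTable, cfg: McmcConfig,
                      scheme: BinScheme | None = None,
                      params: ModelParams = ModelParams(),
                      rng: np.random.Generator | None = None,
                      ) -> tuple[GenotypeArchive, WeightTable]:
    """Fixed-weight multicanonical sampling.

    Runs the same walk with S frozen at ``weights.log_dos`` and records the
    current genotype every ``sample_interval_mcs`` MCS.  Returns the sample
    archive (tagged with fitness and bin) and a copy of the weight table
    whose histogram holds the per-trial bin visits of this phase (flat over
    occupied bins when the weights have converged).  Moves into bins never
    visited during weight determination are always accepted so new regions
    are still reported.
    """
    rng = as_generator(cfg.seed if rng is None else rng)
    scheme = scheme or weights.scheme
    n_samples = cfg.n_mcs // cfg.sample_interval_mcs
    if n_samples < 1:
        raise ValueError("n_mcs shorter than one sampling interval")
    stride = cfg.sample_interval_mcs * cfg.trials(g0)
    n = g0.n_genes
    mats = np.empty((n_samples, n * n), dtype=np.int8)
    fvals = np.empty(n_samples)
    bins = np.empty(n_samples, dtype=np.int64)
    bin_hist = np.zeros(scheme.n_bins, dtype=np.int64)
    log_dos = np.where(weights.visited, weights.log_dos, 0.0)
    _kernels.entropic_walk(
        g0._lin(), n, g0.input_gene, g0.output_gene,
        params.alpha, params.mu, params.steady_tol, params.max_steps,
        scheme.n_bins, log_dos, weights.visited.copy(),
        n_samples, stride, kernel_seed(rng), mats, fvals, bins, bin_hist)
    archive = GenotypeArchive(g0.input_gene, g0.output_gene)
    for i in range(n_samples):
        archive.add(mats[i].reshape(n, n), fvals[i], bin=int(bins[i]))
    visit_table = WeightTable(weights.log_dos.copy(), bin_hist,
                              weights.visited.copy(), 0.0, scheme,
                              weights.converged)
    return archive, visit_table


def genotypic_entropy(weights: WeightTable) -> np.ndarray:
    """Per-bin genotypic entropy log N(f), normalised to 0 in the lowest bin.

    Unvisited bins are NaN.
    """
    if not weights.visited[0]:
        raise ValueError("lowest fitness bin unvisited; cannot normalise")
    out = weights.log_dos - weights.log_dos[0]
    out = np.where(weights.visited, out, np.nan)
    return out
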