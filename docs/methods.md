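# Methods

## Model

A gene regulatory network (GRN) is a signed directed graph on `N` genes,
stored as a matrix `J` with entries in {−1, 0, +1}: `J[i, j]` is the
regulation of gene `i` by gene `j` (+1 activation, −1 repression, 0 none);
self-loops are allowed.  Gene 0 receives an external input `I` added to its
regulatory sum; one designated output gene (gene 1 by convention,
configurable) is read out.  Expression levels evolve by the synchronous
discrete-time map

    x_i(t+1) = R( I·δ_{i,0} + Σ_j J_ij x_j(t) ),     R(y) = 1 / (1 + e^{−α(y−μ)}).

Defaults are α = 2.0 and μ = 0.424, for which an unregulated gene settles at
the "spontaneous" level R(0) ≈ 0.29986 ≈ 0.3.  All runs are initialised at
R(0) exactly (the true fixed point of an unregulated gene), not at the
rounded 0.3.

**Fitness** measures history-dependent switching: run to steady state at
I = 0 from the spontaneous state, then — *without resetting expression* —
switch to I = 1 and run to steady state again;
`f = max(x_out(1) − x_out(0), 0)`.  Continuing phase 2 from the phase-1
state is what lets bistable genotypes earn high fitness.

**Mutation** is a single-edge rewiring: cut one uniformly chosen edge, then
place an edge of uniform random sign on a uniformly chosen cell that is
empty after the cut (the cut cell included).  This keeps the edge count `K`
fixed and makes the proposal symmetric: each forward move has a reverse move
of equal probability, as required for the Monte Carlo samplers.

## Steady states, limit cycles, and tolerances

The model itself does not prescribe a convergence rule, so the following
choices are explicit package defaults:

* Convergence: max-abs change of expression between consecutive steps
  < `steady_tol` = 1e−9 (well below the 1e−6 threshold used by the
  phenotype classifier, so classification is tolerance-robust), with an
  iteration cap `max_steps` = 10 000.
* Limit cycles (possible under synchronous updates with repression): cycles
  are detected on the fly by Brent's tortoise-and-hare comparison at the
  same tolerance and summarised as the element-wise mean over one full
  period, flagged `converged=False`.  If the cap is reached with no cycle
  found (quasi-periodic or chaotic trajectories), the mean over the final
  100 states is returned instead.  Either way every genotype gets a
  deterministic, reproducible surrogate state — and hence a defined fitness
  and phenotype — with the non-convergence flag carried through to outputs.
* The response exponent is saturated at ±700 to avoid floating overflow.

All inner loops (steady-state iteration, fitness, sweeps, the Monte Carlo
walkers) are numba-compiled; the public API wraps them with validated
dataclasses.  Kernel randomness is seeded from the injected numpy Generator,
so a single seed reproduces every run.

## Phenotype classification

Quasi-static sweep with state continuation: equilibrate at I = 0 from the
spontaneous state, then raise I in steps of 0.005 (inclusive grid, 201
points on [0, 1]), re-running to steady state from the previous steady
state; then sweep back down starting from the I = 1 steady state.  With
ε = 1e−6:

* **monostable** — up and down trajectories agree everywhere (< ε);
* **one-way switch** — the trajectories differ at I = 0 by > ε (the output
  never returns: only one saddle-node bifurcation in range);
* **toggle switch** — otherwise (hysteresis whose loop closes in range).

The one-way test is evaluated before the toggle test: a nonzero endpoint
gap implies irreversibility regardless of intermediate behaviour.

Extended sweeps (default I ∈ [−10, 10], step 0.01) refine one-way switches:
`intrinsically_one_way` if the down sweep never rejoins the low branch
anywhere in the range, else `off_range_toggle` (the loop closes at I < 0).
Jumps — adjacent-grid output changes above `jump_eps` = 0.1 — locate the
saddle-node transitions; 0.1 is an order of magnitude above smooth per-step
changes at this grid yet far below branch separation.  Oscillatory
genotypes are classified from their averaged surrogate states and flagged
(`all_converged=False`); they have no rigorous label under this scheme.

Classifier correctness is checked against an independent brute-force oracle
on small genotypes: enumerate coexisting stable fixed points by iterating
the map from many random initial states at each of a grid of inputs, and
require that sweep-detected hysteresis coincide with oracle multistability.

## Multicanonical sampling

Fitness is divided into 100 equal bins ([k/100, (k+1)/100), the last bin
closed at 1).  Because high-fitness genotypes are exponentially rare, the
reference ensemble is built by flat-histogram Monte Carlo:

1. **Wang-Landau**: a random walk with rewiring proposals and acceptance
   min(1, exp(S_old − S_new)), where S is the running per-bin log
   density-of-states estimate; after every trial the current bin's S is
   raised by the modification factor and the visit histogram incremented.
   When the histogram over visited bins is flat (min ≥ 0.8 × mean) the
   factor halves and the histogram resets; the run stops at a final
   increment of 1e−4 (desk-scale default; configurable).  The schedule
   values are standard Wang-Landau practice — the method's original
   description fixes none of them — and the sampler is validated against
   exact enumeration rather than against the schedule.
2. **Entropic sampling**: the same walk with S frozen, recording the
   current genotype every 20 MCS (1 MCS = K rewiring trials).  With
   converged weights each bin is visited evenly and genotypes within a bin
   appear with equal probability.  Proposals into bins never visited during
   weight determination are accepted unconditionally so new regions are
   still reported; the count of such moves is returned.

Genotypic entropy log N(f) is the converged S shifted so the lowest bin
([0, 0.01)) is zero.

On the fully enumerable two-gene, two-edge space (24 genotypes) the sampler
reproduces exact per-bin log counts within 0.2 nats and uniform within-bin
composition (chi-square); the fixed-weight chain passes an empirical
detailed-balance (flow symmetry) check.

## Evolutionary simulators

Both simulators use a population of 1000 random genotypes (defaults
N = 40, K = 120), preserve 500 survivors per generation unchanged, and add
one rewired copy of each survivor.

* **ESh** (truncation): survivors are the 500 highest-fitness members, ties
  broken uniformly at random.  Max fitness is exactly non-decreasing.  Runs
  stop at 150 generations — short transients already reach very high
  fitness — and parent links allow tracing the best final member's lineage
  back to generation 0.
* **ESr** (stochastic steady state): each member scores
  P = e^{βf} · r with r ~ U[0, 1] (ranked as log P = βf + log r to avoid
  overflow at large β), and the top 500 P survive.  β = 0.4 by default.
  After a burn-in (default 10 × the sampling stride; stride 100
  generations) the preserved members are archived every stride.  Steady
  state can be verified by comparing the fitness distributions of the first
  and second archive halves.

## Robustness and structure

* **Essential edges**: an edge is essential when fitness after cutting that
  single edge is below 0.5 — a threshold on the post-cut fitness itself,
  not on the drop from baseline, and meaningful only for genotypes with
  baseline fitness well above 0.5.  All K cuts are evaluated with exactly
  the baseline steady-state protocol (no caching across topologies).
* **Lethal-mutation ratio**: the fraction of (default 1000) independent
  single-edge rewirings of the original genotype that push fitness below
  the same threshold.  N_ee and r_l correlate strongly, so N_ee is the
  cheap deterministic robustness proxy.
* **++++ motif**: auto-activation of input and output plus mutual
  activation between them — a pure-structure check of four matrix cells.
* **Network reduction**: from a genotype with fitness above 0.8, delete
  uniformly random edges, keeping each deletion only while fitness stays
  above 0.8; the first rejected deletion ends the pass.  1000 independent
  passes are run and the fewest-edge result kept; the whole procedure
  repeats on that result until a round yields no further reduction.  A
  failed deletion ends a pass (rather than retrying another edge) because
  the restarts exist precisely to explore alternative deletion orders.
  The result is audited for local minimality in tests by exhaustively
  re-trying every single remaining deletion.
* **Cut-outcome census**: each essential-edge cut genotype is classified on
  the extended input range into intrinsically one-way / toggle /
  monostable.

## Desk-scale study conditions

Full-scale reference runs (1e8 MCS; tens of thousands of lineages; 1e6-plus
ESr generations) are supported by configuration but are not what the test
suite runs.  The bundled comparison study uses a 20-gene, 60-edge system:
Wang-Landau budget 6e4 MCS with final increment 1e−3, entropic sampling
1e5 MCS at stride 2 MCS, and ESr with pop 1000 / keep 500 / β = 0.4 /
8e3 generations.  This is the smallest system (from a feasibility scan over
N = 10–20 at fixed edge density K = 3N) whose ESr steady state still
populates the focal bin f ∈ [0.9, 0.91) with ≥ 200 samples at desk-scale
runtimes.  At this scale the second-order-selection signals are directional
and strongly significant: the evolved ensemble shows a markedly lower
one-way-switch fraction and essential-edge count than the multicanonical
reference in the same fitness bin, and within the reference ensemble
monostable genotypes are more robust than one-way switches.

Known desk-scale deviations from the full-size model: the ESr steady-state
fitness distribution is broad (roughly f ∈ 0.15–0.85) rather than
concentrated in a narrow band just below 0.95, and absolute phenotype
fractions and N_ee distributions are not comparable to full-scale values —
only the directional comparisons are.

## What the synthetic fixtures do and do not emulate

The fixture generators produce random genotypes (uniform cells, uniform
signs, exact K), random DAG genotypes (guaranteed monostable — used for
convergence properties), a serial activation chain (every edge on the
unique input-output path), the two-gene ++++ motif, cores padded with
provably fitness-inert appendage edges, and exhaustive enumerations of tiny
genotype spaces (the sampler oracle).  They emulate the model's own genotype
distribution, not any empirical GRN: no degree heterogeneity, no scale-free
structure, no biological edge-sign biases.  Passing tests therefore
demonstrate correctness of the algorithms on the model's assumptions, not
fidelity to measured regulatory networks.

## Known limitations

* Synchronous deterministic dynamics only: no ODE limit, no expression
  noise; N and K are fixed within a run.
* The phenotype scheme is practical rather than rigorous: oscillators are
  labelled from averaged surrogates and flagged; no continuation-based
  bifurcation tracking.
* Wang-Landau refinements (1/t schedule, replica exchange) are out of
  scope; long runs rely on merging independent replicates.
* Network reduction is stochastic descent with restarts; local minimality
  is guaranteed only with high probability, rising with the restart count.
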