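# grnevo

A toolkit for studying **phenotype selection by mutational robustness** in an
abstract gene-regulatory-network (GRN) model: deterministic discrete-time
expression dynamics with a history-dependent switching fitness, a
multicanonical (Wang-Landau + entropic) Monte Carlo sampler that builds an
unbiased reference ensemble across the whole fitness range, two evolutionary
simulators, and the classifiers and robustness metrics needed to compare the
two ensembles.

It is aimed at researchers in evolutionary systems biology who want to ask:
*of all genotypes that achieve a given fitness, which phenotypes does
evolution actually reach?*  When several phenotypes share a fitness level,
evolution favours the mutationally robust ones — a second-order selection
bias invisible to fitness alone.  Quantifying it requires both a reference
ensemble (what exists) and evolved ensembles (what evolution finds).

## Model

A genotype is a signed regulation matrix `J` with entries in {−1, 0, +1}
(`J[i,j]`: regulation of gene *i* by gene *j*; self-loops allowed), one
input gene receiving an external signal `I` and one output gene.
Expression follows the synchronous map

    x_i(t+1) = R( I·δ_{i,0} + Σ_j J_ij x_j(t) ),    R(y) = 1/(1 + e^{−α(y−μ)})

with α = 2.0, μ = 0.424 (spontaneous level R(0) ≈ 0.3).  Fitness is the
history-dependent switch gain

    f = max( x_out(1) − x_out(0), 0 ),

where `x_out(0)` is the steady output at I = 0 from the spontaneous state
and `x_out(1)` the steady output at I = 1 continued *from the I = 0 steady
state*.  Under quasi-static input sweeps every genotype is one of three
phenotypes: **monostable**, **toggle switch** (hysteresis loop closing in
range), or **one-way switch** (irreversible; only one saddle-node
bifurcation in range).  Mutational robustness is measured by the number of
essential edges `N_ee` (single cuts dropping f below 0.5) and the lethal
single-rewiring ratio `r_l`.

Simulation components: `wang_landau` / `entropic_sampling` (flat-histogram
sampling over 100 fitness bins, yielding genotypic entropy log N(f) and
per-bin uniform genotype samples), `esh_run` (truncation selection,
transient adaptation, lineage tracing) and `esr_run` (stochastic selection
P = e^{βf}·r, steady-state evolution), plus `classify`/`classify_extended`,
`essential_edges`, `lethal_ratio`, `motif_report`, `reduce_network` and
`compare_ensembles`.  See `docs/methods.md` for the full method account.

## Worked example

```python
import grnevo as ge

params = ge.ModelParams()                 # alpha=2.0, mu=0.424
print(ge.spontaneous_level(params))       # 0.299852571390463

g = ge.two_gene_pppp()                    # the ++++ motif: all four
fv = ge.fitness(g, params)                # activations on two genes
print(fv.f, fv.x_out_0, fv.x_out_1)
# 0.004285228339670932 0.9504411039111411 0.954726332250812
print(ge.classify(g, params).label)       # monostable

traj = ge.sweep(g, -10.0, 10.0, 0.01, params)
print(traj.outputs.max() - traj.outputs.min())
# 0.3804598449640366
```

The ++++ motif — mutual activation of input and output genes plus both
auto-activation loops — is the core structure of mutationally robust
one-way switches, yet in isolation it is worthless: both fitness phases sit
on its high branch (x_out ≈ 0.95 at I = 0 and I = 1, so f ≈ 0.004, not
0.95 − 0.3), it classifies as monostable, and even across the extended
input range I ∈ [−10, 10] its output moves by only ≈ 0.38 (~0.4).  High
fitness and bistability in range require the surrounding network.

A desk-scale ensemble comparison from the shell:

```sh
grnevo mcmc --n-genes 20 --k-edges 60 --wl-mcs 60000 --n-mcs 100000 \
            --sample-every 2 --seed 1 --out runs/mcmc
grnevo esr  --pop 1000 --keep 500 --beta 0.4 --generations 8000 \
            --n-genes 20 --k-edges 60 --seed 1 --out runs/esr
grnevo compare --archive-a runs/mcmc/samples.json \
               --archive-b runs/esr/esr_samples.json --bin 90 --out cmp.csv
```

`cmp.csv` tabulates, for fitness bin [0.90, 0.91), each method's phenotype
fractions (summing to one, with 3×-standard-error columns) and mean
essential-edge count.  At this scale the evolved archive shows roughly a
0.14 one-way-switch fraction and mean N_ee ≈ 5, against 0.39 and ≈ 15 for
the multicanonical reference: evolution strongly suppresses the fragile
one-way switches that dominate the unbiased ensemble.

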