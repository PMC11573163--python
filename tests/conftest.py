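import numpy as np
import pytest

from grnevo import (EvolutionConfig, ModelParams, esh_run, fitness,
                    reduce_network, serial_chain, two_gene_pppp)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def pppp():
    return two_gene_pppp()


@pytest.fixture(scope="session")
def chain3():
    """Serial activation chain input -> gene2 -> output."""
    return serial_chain(3)


@pytest.fixture(scope="session")
def evolved_genotype(params):
    """A high-fitness genotype found by a short truncation-selection run.

    Session-cached; the seed is fixed so every collection sees the same
    genotype.  Used by the robustness / reduction tests that need a
    baseline fitness well above the thresholds.
    """
    cfg = EvolutionConfig(pop_size=100, n_keep=50, n_generations=250,
                          n_genes=8, k_edges=20, seed=424)
    history = esh_run(cfg, params)
    pop = history[-1]
    best = pop.matrices[np.argmax(pop.fitness)]
    from grnevo import Genotype
    g = Genotype(8, best.copy())
    assert fitness(g, params).f > 0.8, "search did not reach high fitness"
    return g


@pytest.fixture(scope="session")
def smoke_study(params):
    """Desk-scale reference (McMC) and evolved (ESr) ensembles.

    A 20-gene, 60-edge system: Wang-Landau weights, an entropic-sampling
    archive, and an ESr steady-state archive (pop 1000, keep 500, beta 0.4),
    with the bin f in [0.9, 0.91) members of both arms annotated with
    phenotype and essential-edge count.  Session-cached because several
    slow statistical checks share it.
    """
    import numpy as np
    from grnevo import (BinScheme, McmcConfig, annotate_archive,
                        entropic_sampling, esr_run, random_genotype,
                        wang_landau)

    n_genes, k_edges = 20, 60
    scheme = BinScheme(100)
    rng = np.random.default_rng(20260919)
    g0 = random_genotype(n_genes, k_edges, rng)
    weights = wang_landau(
        g0, McmcConfig(n_mcs=60_000, wl_final_increment=1e-3,
                       flatness_check_interval=10_000),
        scheme, params, rng)
    mcmc_samples, _ = entropic_sampling(
        g0, weights, McmcConfig(n_mcs=100_000, sample_interval_mcs=2),
        scheme, params, rng)
    esr_archive = esr_run(
        EvolutionConfig(pop_size=1000, n_keep=500, n_generations=8000,
                        beta=0.4, sample_every=100, n_genes=n_genes,
                        k_edges=k_edges, seed=777),
        params)
    mc90 = mcmc_samples.select(mcmc_samples.bin_indices(scheme) == 90)
    es90 = esr_archive.select(esr_archive.bin_indices(scheme) == 90)
    return {
        "n_genes": n_genes,
        "k_edges": k_edges,
        "scheme": scheme,
        "weights": weights,
        "mcmc": mcmc_samples,
        "esr": esr_archive,
        "mc90": mc90,
        "es90": es90,
        "df_mc90": annotate_archive(mc90, params, scheme),
        "df_es90": annotate_archive(es90, params, scheme),
    }


@pytest.fixture(scope="session")
def minimal_core(evolved_genotype, params):
    """The evolved genotype stripped to a locally minimal functional core."""
    red = reduce_network(evolved_genotype, params, f_threshold=0.8,
                         n_restarts=200, seed=7)
    return red.genotype
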