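"""Response function, dynamics, fitness and the rewiring mutation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from grnevo import (ExpressionState, Genotype, ModelParams, fitness,
                    acyclic_random_genotype, random_genotype, response,
                    rewire, run_to_steady, serial_chain, spontaneous_level,
                    spontaneous_state, step, two_gene_pppp)


def closed_form_R(y, alpha=2.0, mu=0.424):
    """Independent closed-form evaluation of the response function."""
    import math
    return 1.0 / (1.0 + math.exp(-alpha * (y - mu)))


class TestResponse:
    @pytest.mark.parametrize("y, expected", [
        (0.424, 0.5),                      # y = mu gives exactly 1/2
        (0.0, closed_form_R(0.0)),         # spontaneous level, ~0.2999
        (1.0, closed_form_R(1.0)),         # ~0.7599
        (0.6, closed_form_R(0.6)),         # ~0.5870
    ])
    def test_matches_closed_form(self, y, expected, params):
        assert response(y, params) == pytest.approx(expected, abs=1e-12)

    def test_spontaneous_is_point_three(self, params):
        assert spontaneous_level(params) == pytest.approx(0.3, abs=5e-4)

    @pytest.mark.parametrize("mu, expected", [
        (0.0, 0.5),
        (1.0, closed_form_R(0.0, mu=1.0)),  # ~0.1192
    ])
    def test_spontaneous_other_thresholds(self, mu, expected):
        assert spontaneous_level(ModelParams(mu=mu)) == pytest.approx(
            expected, abs=1e-12)

    def test_strictly_increasing_and_bounded(self, params):
        # floating point saturates past |y| ~ 16, so check strictness there
        grid = np.linspace(-15, 15, 2001)
        vals = response(grid, params)
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals > 0) & (vals < 1))

    def test_overflow_guard(self, params):
        # extreme inputs stay finite in (0, 1] instead of overflowing
        lo, hi = response(-1e9, params), response(1e9, params)
        assert np.isfinite(lo) and np.isfinite(hi)
        assert 0.0 <= lo < 1e-300
        assert hi == 1.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(alpha=0.0)
        with pytest.raises(ValueError):
            ModelParams(steady_tol=0.0)


class TestGenotype:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Genotype(2, np.full((2, 2), 2, dtype=np.int8))
        with pytest.raises(ValueError):
            Genotype(2, np.zeros((3, 3), dtype=np.int8))
        with pytest.raises(ValueError):
            Genotype(2, np.zeros((2, 2), dtype=np.int8), input_gene=0,
                     output_gene=0)
        with pytest.raises(ValueError):
            Genotype(2, np.zeros((2, 2), dtype=np.int8), output_gene=5)

    def test_edges_roundtrip_matrix(self, rng):
        g = random_genotype(6, 10, rng)
        mat = np.zeros((6, 6), dtype=np.int8)
        for src, tgt, sign in g.edges():
            mat[tgt, src] = sign
        assert np.array_equal(mat, g.regulation)


class TestStep:
    def test_no_regulation_no_input(self, params):
        g = Genotype(3, np.zeros((3, 3), dtype=np.int8))
        state = ExpressionState(np.array([0.1, 0.5, 0.9]), input_value=0.0)
        out = step(state, g, params)
        assert np.allclose(out.levels, closed_form_R(0.0))

    def test_input_gene_only_receives_input(self, params):
        g = Genotype(3, np.zeros((3, 3), dtype=np.int8))
        state = ExpressionState(np.zeros(3), input_value=1.0)
        out = step(state, g, params)
        assert out.levels[0] == pytest.approx(closed_form_R(1.0), abs=1e-12)
        assert np.allclose(out.levels[1:], closed_form_R(0.0))

    def test_pppp_single_step(self, pppp, params):
        state = ExpressionState(np.array([0.3, 0.3]))
        out = step(state, pppp, params)
        assert np.allclose(out.levels, closed_form_R(0.6), atol=1e-12)

    def test_maps_into_open_unit_interval(self, params, rng):
        g = random_genotype(8, 20, rng)
        state = ExpressionState(rng.random(8), input_value=0.7)
        out = step(state, g, params)
        assert np.all((out.levels > 0) & (out.levels < 1))

    def test_dimension_mismatch(self, pppp, params):
        with pytest.raises(ValueError):
            step(ExpressionState(np.zeros(3)), pppp, params)


def iterate_fixed_point(fn, x0=0.3, tol=1e-12):
    """Plain-python fixed-point oracle, independent of the kernels."""
    x = x0
    for _ in range(100_000):
        xn = fn(x)
        if abs(xn - x) < tol:
            return xn
        x = xn
    raise AssertionError("oracle iteration did not converge")


class TestRunToSteady:
    def test_unregulated_fast_convergence(self, params):
        g = Genotype(4, np.zeros((4, 4), dtype=np.int8))
        state, conv = run_to_steady(g, 0.0, params=params)
        assert conv
        assert np.allclose(state.levels, closed_form_R(0.0), atol=1e-8)

    def test_single_edge_chain(self, params):
        g = serial_chain(2)          # input -> output, +1
        state, conv = run_to_steady(g, 0.0, params=params)
        assert conv
        # output = R(R(0))
        assert state.levels[1] == pytest.approx(
            closed_form_R(closed_form_R(0.0)), abs=1e-8)

    def test_pppp_upper_branch(self, pppp, params):
        expected = iterate_fixed_point(lambda x: closed_form_R(2 * x))
        state, conv = run_to_steady(pppp, 0.0, params=params)
        assert conv
        assert np.allclose(state.levels, expected, atol=1e-7)

    def test_period_two_cycle_flagged_and_averaged(self, params):
        # negative self-loop with strong alternation: x -> R(-x) oscillates
        # for steep alpha; flagged non-convergent, value is the cycle mean
        steep = ModelParams(alpha=30.0, mu=0.0)
        g = Genotype(2, np.array([[-1, 0], [0, 0]], dtype=np.int8))
        state, conv = run_to_steady(g, 0.0, params=steep)
        assert not conv
        a = 0.5
        seen = []
        for _ in range(10_000):
            a = closed_form_R(-a, alpha=30.0, mu=0.0)
            seen.append(a)
        assert state.levels[0] == pytest.approx(np.mean(seen[-2:]), abs=1e-6)


class TestFitness:
    def test_unregulated_zero(self, params):
        g = Genotype(3, np.zeros((3, 3), dtype=np.int8))
        fv = fitness(g, params)
        assert fv.f == 0.0
        assert fv.x_out_0 == pytest.approx(fv.x_out_1, abs=1e-8)

    def test_single_edge_value(self, params):
        fv = fitness(serial_chain(2), params)
        x0 = closed_form_R(closed_form_R(0.0))
        x1 = closed_form_R(closed_form_R(1.0))
        assert fv.x_out_0 == pytest.approx(x0, abs=1e-8)
        assert fv.x_out_1 == pytest.approx(x1, abs=1e-8)
        assert fv.f == pytest.approx(x1 - x0, abs=1e-8)   # ~0.2237

    def test_pppp_low_fitness(self, pppp, params):
        # both phases sit on the high branch; the motif alone is not a switch
        fv = fitness(pppp, params)
        assert fv.f == pytest.approx(0.004, abs=2e-3)
        assert fv.f < 0.1

    def test_bounded_and_clamped(self, params, rng):
        for _ in range(25):
            fv = fitness(random_genotype(6, 10, rng), params)
            assert 0.0 <= fv.f <= 1.0
            if fv.x_out_1 <= fv.x_out_0:
                assert fv.f == 0.0


class TestRewire:
    def test_conserves_edge_count_and_alphabet(self, rng):
        g = random_genotype(5, 8, rng)
        for _ in range(200):
            g = rewire(g, rng)
            assert g.n_edges == 8
            assert set(np.unique(g.regulation)) <= {-1, 0, 1}

    def test_proposal_uniform_on_two_gene_space(self, rng):
        # 1 edge on a 2-gene matrix: the move cuts it and refills any of the
        # 4 cells with either sign -> 8 equally likely outcomes
        g = Genotype(2, np.array([[1, 0], [0, 0]], dtype=np.int8))
        counts = {}
        n = 10_000
        for _ in range(n):
            out = rewire(g, rng)
            cell = int(np.flatnonzero(out.regulation)[0])
            sign = int(out.regulation.reshape(-1)[cell])
            counts[(cell, sign)] = counts.get((cell, sign), 0) + 1
        assert len(counts) == 8
        chi2, p = stats.chisquare(list(counts.values()))
        assert p > 1e-3

    def test_errors_on_degenerate_matrices(self, rng):
        with pytest.raises(ValueError):
            rewire(Genotype(2, np.zeros((2, 2), dtype=np.int8)), rng)
        with pytest.raises(ValueError):
            rewire(two_gene_pppp(), rng)   # fully connected


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_acyclic_genotypes_always_converge(seed):
    """No directed feedback -> the cascade settles exactly."""
    rng = np.random.default_rng(seed)
    g = acyclic_random_genotype(7, 12, rng)
    fv = fitness(g)
    assert fv.converged
    state, conv = run_to_steady(g, 0.37)
    assert conv


@settings(max_examples=15, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_fitness_deterministic_and_bounded(seed):
    rng = np.random.default_rng(seed)
    g = random_genotype(8, 20, rng)
    f1 = fitness(g).f
    f2 = fitness(g).f
    assert f1 == f2
    assert 0.0 <= f1 <= 1.0
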