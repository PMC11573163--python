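"""Numba-compiled inner loops.

Everything here operates on the regulation matrix as a flat float64 array of
length ``n * n`` (C order, ``J[i, j] = Jlin[i * n + j]`` with gene ``j``
regulating gene ``i``).  The public modules wrap these kernels with the
documented dataclasses; no kernel is part of the public API.

Random numbers inside kernels come from numba's internal Mersenne Twister,
seeded explicitly per call; the wrappers derive those seeds from the injected
numpy Generator so that every run is reproducible from a single seed.
"""

import numpy as np
from numba import njit

#: window length used to average non-convergent (oscillatory) trajectories
AVG_WINDOW = 100


@njit(cache=True, inline="always")
def response_scalar(y, alpha, mu):
    z = -alpha * (y - mu)
    if z > 700.0:
        z = 700.0
    elif z < -700.0:
        z = -700.0
    return 1.0 / (1.0 + np.exp(z))


@njit(cache=True, inline="always")
def _one_step(Jlin, n, input_value, input_gene, alpha, mu, x, xn):
    for i in range(n):
        s = input_value if i == input_gene else 0.0
        base = i * n
        for j in range(n):
            s += Jlin[base + j] * x[j]
        xn[i] = response_scalar(s, alpha, mu)


@njit(cache=True)
def steady_state(Jlin, n, input_value, x_init, input_gene,
                 alpha, mu, tol, max_steps):
    """Iterate the synchronous dynamics until the max-abs change is < tol.

    Returns ``(x, converged)``.  Limit cycles are detected on the fly with
    Brent's algorithm (distance to a lagging reference state < tol) and
    summarised as the element-wise mean over one full period, flagged
    ``converged=False``.  If ``max_steps`` is exhausted with no cycle found
    (quasi-periodic or chaotic trajectories), the mean over the final
    AVG_WINDOW states is returned instead.
    """
    x = x_init.copy()
    xn = np.empty(n)
    ref = x_init.copy()       # Brent's lagging reference state
    power = 1
    lam = 0
    window = np.zeros((AVG_WINDOW, n))
    steps_done = 0
    for t in range(max_steps):
        _one_step(Jlin, n, input_value, input_gene, alpha, mu, x, xn)
        d = 0.0
        for i in range(n):
            dd = abs(xn[i] - x[i])
            if dd > d:
                d = dd
        if d < tol:
            return xn.copy(), True
        lam += 1
        dref = 0.0
        for i in range(n):
            dd = abs(xn[i] - ref[i])
            if dd > dref:
                dref = dd
        if dref < tol:
            # limit cycle of period lam: average over one full period
            period = lam
            out = np.zeros(n)
            for i in range(n):
                x[i] = xn[i]
                out[i] = xn[i]
            for _ in range(period - 1):
                _one_step(Jlin, n, input_value, input_gene, alpha, mu, x, xn)
                for i in range(n):
                    out[i] += xn[i]
                    x[i] = xn[i]
            for i in range(n):
                out[i] /= period
            return out, False
        if lam == power:
            power *= 2
            lam = 0
            for i in range(n):
                ref[i] = xn[i]
        row = t % AVG_WINDOW
        for i in range(n):
            x[i] = xn[i]
            window[row, i] = xn[i]
        steps_done = t + 1
    m = min(steps_done, AVG_WINDOW)
    out = np.zeros(n)
    for r in range(m):
        for i in range(n):
            out[i] += window[r, i]
    for i in range(n):
        out[i] /= m
    return out, False


@njit(cache=True)
def fitness_eval(Jlin, n, input_gene, output_gene, alpha, mu, tol, max_steps):
    """Two-phase fitness: steady output at I=0 from the spontaneous state,
    then at I=1 continuing from the I=0 steady state.

    Returns ``(f, x_out_0, x_out_1, converged_0, converged_1)``.
    """
    x0 = np.full(n, response_scalar(0.0, alpha, mu))
    s0, c0 = steady_state(Jlin, n, 0.0, x0, input_gene, alpha, mu, tol, max_steps)
    s1, c1 = steady_state(Jlin, n, 1.0, s0, input_gene, alpha, mu, tol, max_steps)
    f = s1[output_gene] - s0[output_gene]
    if f < 0.0:
        f = 0.0
    return f, s0[output_gene], s1[output_gene], c0, c1


@njit(cache=True)
def fitness_many(Jstack, n, input_gene, output_gene, alpha, mu, tol, max_steps):
    """Fitness of a stack of flattened regulation matrices (P, n*n)."""
    p = Jstack.shape[0]
    out = np.empty(p)
    for k in range(p):
        f, _, _, _, _ = fitness_eval(Jstack[k], n, input_gene, output_gene,
                                     alpha, mu, tol, max_steps)
        out[k] = f
    return out


@njit(cache=True)
def sweep_outputs(Jlin, n, grid, x_init, input_gene, output_gene,
                  alpha, mu, tol, max_steps):
    """Quasi-static sweep with state continuation along ``grid``.

    The state used for grid[0] is ``x_init``; each later grid point restarts
    from the previous steady (or averaged surrogate) state.  Returns
    ``(outputs, converged_flags, final_state)``.
    """
    m = grid.shape[0]
    outs = np.empty(m)
    conv = np.zeros(m, np.bool_)
    x = x_init.copy()
    for k in range(m):
        x, c = steady_state(Jlin, n, grid[k], x, input_gene,
                            alpha, mu, tol, max_steps)
        outs[k] = x[output_gene]
        conv[k] = c
    return outs, conv, x


# ---------------------------------------------------------------------------
# Monte Carlo walkers (Wang-Landau weight determination, entropic sampling)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _bin_of(f, n_bins):
    b = int(f * n_bins)
    if b >= n_bins:
        b = n_bins - 1
    if b < 0:
        b = 0
    return b


@njit(cache=True)
def _build_cell_lists(Jlin, ncells, edges, empties, slot_of, is_edge):
    ne = 0
    nz = 0
    for c in range(ncells):
        if Jlin[c] != 0.0:
            edges[ne] = c
            slot_of[c] = ne
            is_edge[c] = True
            ne += 1
        else:
            empties[nz] = c
            slot_of[c] = nz
            is_edge[c] = False
            nz += 1
    return ne, nz


@njit(cache=True, inline="always")
def _propose(Jlin, edges, empties, n_edges, n_empty):
    """Draw a single-edge rewiring: returns (cut_cell, new_cell, sign).

    The cut cell itself is eligible as the refill target (identity and
    sign-flip moves are possible), so the refill target is uniform over the
    ``n_empty + 1`` cells that are empty after the cut.
    """
    cut = edges[np.random.randint(0, n_edges)]
    t = np.random.randint(0, n_empty + 1)
    new = cut if t == n_empty else empties[t]
    sign = 1.0 if np.random.random() < 0.5 else -1.0
    return cut, new, sign


@njit(cache=True, inline="always")
def _apply_move(Jlin, cut, new, sign):
    Jlin[cut] = 0.0
    Jlin[new] = sign


@njit(cache=True, inline="always")
def _commit_lists(edges, empties, slot_of, is_edge, cut, new):
    if cut == new:
        return
    e_slot = slot_of[cut]
    z_slot = slot_of[new]
    edges[e_slot] = new
    empties[z_slot] = cut
    slot_of[new] = e_slot
    slot_of[cut] = z_slot
    is_edge[new] = True
    is_edge[cut] = False


@njit(cache=True)
def wang_landau_walk(Jlin, n, input_gene, output_gene, alpha, mu, tol,
                     max_steps, n_bins, log_dos, hist, visited,
                     ln_f_init, flatness, ln_f_final,
                     check_interval, max_trials, seed):
    """Wang-Landau determination of per-fitness-bin log density of states.

    Mutates log_dos / hist / visited and Jlin in place.  Returns
    ``(trials_used, final_increment)``; convergence is reached when the
    increment falls below ``ln_f_final``.
    """
    np.random.seed(seed)
    ncells = n * n
    edges = np.empty(ncells, np.int64)
    empties = np.empty(ncells, np.int64)
    slot_of = np.empty(ncells, np.int64)
    is_edge = np.zeros(ncells, np.bool_)
    n_edges, n_empty = _build_cell_lists(Jlin, ncells, edges, empties,
                                         slot_of, is_edge)
    f, _, _, _, _ = fitness_eval(Jlin, n, input_gene, output_gene,
                                 alpha, mu, tol, max_steps)
    b = _bin_of(f, n_bins)
    ln_f = ln_f_init
    trials = 0
    while ln_f >= ln_f_final and trials < max_trials:
        cut, new, sign = _propose(Jlin, edges, empties, n_edges, n_empty)
        old_cut = Jlin[cut]
        old_new = Jlin[new]
        _apply_move(Jlin, cut, new, sign)
        f2, _, _, _, _ = fitness_eval(Jlin, n, input_gene, output_gene,
                                      alpha, mu, tol, max_steps)
        b2 = _bin_of(f2, n_bins)
        ds = log_dos[b] - log_dos[b2]
        if ds >= 0.0 or np.random.random() < np.exp(ds):
            _commit_lists(edges, empties, slot_of, is_edge, cut, new)
            b = b2
            f = f2
        else:
            Jlin[new] = old_new
            Jlin[cut] = old_cut
        log_dos[b] += ln_f
        hist[b] += 1
        visited[b] = True
        trials += 1
        if trials % check_interval == 0:
            hmin = np.inf
            hsum = 0.0
            nvis = 0
            for k in range(n_bins):
                if visited[k]:
                    nvis += 1
                    hsum += hist[k]
                    if hist[k] < hmin:
                        hmin = hist[k]
            if nvis > 0 and hmin >= flatness * (hsum / nvis):
                ln_f *= 0.5
                for k in range(n_bins):
                    hist[k] = 0
    return trials, ln_f


@njit(cache=True)
def entropic_walk(Jlin, n, input_gene, output_gene, alpha, mu, tol, max_steps,
                  n_bins, log_dos, visited, n_samples, stride_trials, seed,
                  sample_mats, sample_f, sample_bins, bin_hist):
    """Fixed-weight multicanonical walk recording one sample per stride.

    Acceptance uses min(1, exp(S_old - S_new)); moves touching a bin never
    visited during weight determination are accepted unconditionally so that
    new regions are still reported (their count is returned).
    """
    np.random.seed(seed)
    ncells = n * n
    edges = np.empty(ncells, np.int64)
    empties = np.empty(ncells, np.int64)
    slot_of = np.empty(ncells, np.int64)
    is_edge = np.zeros(ncells, np.bool_)
    n_edges, n_empty = _build_cell_lists(Jlin, ncells, edges, empties,
                                         slot_of, is_edge)
    f, _, _, _, _ = fitness_eval(Jlin, n, input_gene, output_gene,
                                 alpha, mu, tol, max_steps)
    b = _bin_of(f, n_bins)
    novel_moves = 0
    for s in range(n_samples):
        for t in range(stride_trials):
            cut, new, sign = _propose(Jlin, edges, empties, n_edges, n_empty)
            old_cut = Jlin[cut]
            old_new = Jlin[new]
            _apply_move(Jlin, cut, new, sign)
            f2, _, _, _, _ = fitness_eval(Jlin, n, input_gene, output_gene,
                                          alpha, mu, tol, max_steps)
            b2 = _bin_of(f2, n_bins)
            if not (visited[b] and visited[b2]):
                accept = True
                novel_moves += 1
            else:
                ds = log_dos[b] - log_dos[b2]
                accept = ds >= 0.0 or np.random.random() < np.exp(ds)
            if accept:
                _commit_lists(edges, empties, slot_of, is_edge, cut, new)
                b = b2
                f = f2
            else:
                Jlin[new] = old_new
                Jlin[cut] = old_cut
            bin_hist[b] += 1
        for c in range(ncells):
            sample_mats[s, c] = np.int8(Jlin[c])
        sample_f[s] = f
        sample_bins[s] = b
    return novel_moves
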