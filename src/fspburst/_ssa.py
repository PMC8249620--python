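"""Compiled exact-SSA kernel for the time-inhomogeneous gene model.

Sampling uses thinning: candidate event times are drawn against an
upper bound on the total propensity that is exact for the current
(state, count) because the only time-varying term is the single
signal-modulated switching edge, whose future supremum is available in
closed form (the signal rises to one peak and then decays).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._integrate import MODE_ENHANCE, MODE_SUPPRESS_SAT, _edge_rate


@njit(cache=False)
def _edge_rate_future_max(t, mode, k, b, r1, r2, t_peak, s_peak):
    """sup_{u >= t} of the signal-edge rate (valid thinning bound)."""
    if mode == MODE_ENHANCE:
        if t < t_peak:
            return k + b * s_peak
        return k + b * (np.exp(-r1 * t) * (1.0 - np.exp(-r2 * t)))
    # suppressed edge: rate <= basal k for all t (s >= 0)
    return k


@njit(cache=False)
def ssa_batch(seed, init_state, init_count, n_states, ku, kd,
              sig_from, sig_to, mode, k_sig, b_sig, r1, r2,
              alpha, delta, t_grid):
    """Exact trajectories for a batch of i.i.d. cells.

    ku[i]/kd[i] are the basal up/down switching rates out of state i with
    the signal edge zeroed (it is handled separately via k_sig, b_sig).
    Returns (states, counts), each (n_cells, len(t_grid)), sampled at the
    grid times.
    """
    np.random.seed(seed)
    n_cells = init_state.shape[0]
    T = t_grid.shape[0]
    states = np.empty((n_cells, T), dtype=np.int64)
    counts = np.empty((n_cells, T), dtype=np.int64)
    t_peak = np.log(1.0 + r2 / r1) / r2
    s_peak = np.exp(-r1 * t_peak) * (1.0 - np.exp(-r2 * t_peak))
    sig_up = sig_to == sig_from + 1

    for c in range(n_cells):
        t = 0.0
        g = init_state[c]
        x = init_count[c]
        ptr = 0
        while ptr < T and t_grid[ptr] <= t:
            states[c, ptr] = g
            counts[c, ptr] = x
            ptr += 1
        while ptr < T:
            base = ku[g] + kd[g] + alpha[g] + delta * x
            bound = base
            if g == sig_from:
                bound += _edge_rate_future_max(t, mode, k_sig, b_sig, r1, r2,
                                               t_peak, s_peak)
            if bound <= 0.0:
                # frozen cell: no reaction can ever fire again
                while ptr < T:
                    states[c, ptr] = g
                    counts[c, ptr] = x
                    ptr += 1
                break
            tnew = t + (-np.log(np.random.random()) / bound)
            while ptr < T and t_grid[ptr] < tnew:
                states[c, ptr] = g
                counts[c, ptr] = x
                ptr += 1
            if ptr >= T:
                break
            t = tnew
            a_up = ku[g]
            a_down = kd[g]
            if g == sig_from:
                gnow = _edge_rate(t, mode, k_sig, b_sig, r1, r2)
                if sig_up:
                    a_up += gnow
                else:
                    a_down += gnow
            a_tx = alpha[g]
            a_deg = delta * x
            u = np.random.random() * bound
            if u < a_up:
                g += 1
            elif u < a_up + a_down:
                g -= 1
            elif u < a_up + a_down + a_tx:
                x += 1
            elif u < a_up + a_down + a_tx + a_deg:
                x -= 1
            # else: thinned (no reaction)
    return states, counts
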