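"""Compiled inner loop of the facilitated-diffusion target search.

The per-step semantics (release -> search -> bind, in complex-index
order) are documented in :mod:`rddmsim.target_search`; this module only
provides the numba-compiled implementation so that full-scale cycles
(10^7-10^8 complex-steps) run in seconds.  Scanning events are sampled
from a single uniform draw with nested thresholds (exit, else jump,
else slide left/right 50/50), which is distributionally identical to
sequential Bernoulli draws.  Randomness uses numba's internal np.random
state, seeded once per ``run_steps`` call from the caller's generator,
so trajectories are reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

FREE = 0
SCANNING = 1
BOUND = 2
_RELEASED = 3  # freed this step; searches again from the next step

OFF_TARGET = -1
NO_MOLECULE = -2


@njit(inline="always")
def _encounter_one(
    i, tgt, state, mol, pos, rem, occ, rejections,
    p_on, p_self, n_loci, length, max_occ, k_off,
):
    """One free (or jumping) complex lands on a molecule; binds if matched.

    On-target landings hit the complex's cognate locus with probability
    ``p_self`` (sequence-guided bias), otherwise a uniform locus.
    """
    if np.random.random() < p_on:
        if np.random.random() < p_self:
            lid = tgt[i]
        else:
            lid = np.random.randint(0, n_loci)
        p = np.random.randint(0, length)
        if lid == tgt[i]:
            if occ[lid] < max_occ:
                state[i] = BOUND
                mol[i] = lid
                pos[i] = p
                rem[i] = np.random.exponential(1.0 / k_off)
                occ[lid] += 1
            else:
                rejections[lid] += 1
                state[i] = SCANNING
                mol[i] = lid
                pos[i] = p
        else:
            state[i] = SCANNING
            mol[i] = lid
            pos[i] = p
    else:
        state[i] = SCANNING
        mol[i] = OFF_TARGET
        pos[i] = np.random.randint(0, length)


@njit(cache=True)
def run_steps(
    seed, n_steps, dt,
    tgt, state, mol, pos, rem,
    occ, chh, cycle_dwell, rejections,
    p_on, p_self, p_jump, p_exit, length, max_occ, k_off,
    dwell_per_percent, n_loci,
):
    """Advance the whole population ``n_steps`` time steps of length ``dt``.

    Mutates all state arrays in place.  ``dwell_per_percent <= 0`` means
    "accumulate dwell only" (burn-in before calibration); otherwise CHH
    methylation is updated continuously from each step's matched dwell.
    Returns the total matched dwell credited over the call, per locus.
    """
    np.random.seed(seed)
    n = tgt.size
    # nested event thresholds on one uniform: exit | jump | slide L | slide R
    t_exit = p_exit
    t_jump = p_exit + (1.0 - p_exit) * p_jump
    t_left = t_jump + (1.0 - t_jump) * 0.5
    step_dwell = np.zeros(n_loci)
    total_dwell = np.zeros(n_loci)
    for _ in range(n_steps):
        for l in range(n_loci):
            step_dwell[l] = 0.0
        # releases first: credit this step's bound time, free expired complexes
        for i in range(n):
            if state[i] == BOUND:
                credit = rem[i] if rem[i] < dt else dt
                step_dwell[tgt[i]] += credit
                rem[i] -= dt
                if rem[i] <= 0.0:
                    occ[tgt[i]] -= 1
                    state[i] = _RELEASED
                    mol[i] = NO_MOLECULE
        # search: free complexes encounter, scanning complexes take one move
        for i in range(n):
            s = state[i]
            if s == SCANNING:
                u = np.random.random()
                if u < t_exit:
                    state[i] = FREE
                    mol[i] = NO_MOLECULE
                elif u < t_jump:
                    _encounter_one(
                        i, tgt, state, mol, pos, rem, occ, rejections,
                        p_on, p_self, n_loci, length, max_occ, k_off,
                    )
                else:
                    if u < t_left:
                        pos[i] -= 1
                    else:
                        pos[i] += 1
                    if pos[i] < 0 or pos[i] >= length:  # slid off an end
                        state[i] = FREE
                        mol[i] = NO_MOLECULE
            elif s == FREE:
                _encounter_one(
                    i, tgt, state, mol, pos, rem, occ, rejections,
                    p_on, p_self, n_loci, length, max_occ, k_off,
                )
        # continuous methylation update from this step's matched dwell
        for l in range(n_loci):
            d = step_dwell[l]
            if d > 0.0:
                cycle_dwell[l] += d
                total_dwell[l] += d
                if dwell_per_percent > 0.0:
                    chh[l] += 0.01 * d / dwell_per_percent
                    if chh[l] > 1.0:
                        chh[l] = 1.0
        for i in range(n):
            if state[i] == _RELEASED:
                state[i] = FREE
    return total_dwell
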