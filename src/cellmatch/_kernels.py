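"""Compiled inner loops for the Metropolis sampler and the vertex dynamics.

These kernels mirror the pure-Python operations in :mod:`energetics`,
:mod:`mismatch`, :mod:`metropolis` and :mod:`vertex_dynamics` exactly; the
test suite cross-validates them against those reference paths (incremental
energy vs full recomputation, kernel Euler step vs the NumPy step).  State is
mutated in place: ``x`` is the (2, N+1) vertex array, ``types`` the (2, N)
int64 type codes, ``l0`` the (2, N) rest lengths.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def tissue_mismatch_arrays(x: np.ndarray) -> float:
    """Mean sister-pair mismatch from the vertex array alone."""
    n = x.shape[1] - 1
    acc = 0.0
    for i in range(n):
        l1 = x[0, i + 1] - x[0, i]
        l2 = x[1, i + 1] - x[1, i]
        hi = min(x[0, i + 1], x[1, i + 1])
        lo = max(x[0, i], x[1, i])
        ov = hi - lo
        if ov < 0.0:
            ov = 0.0
        m1 = 1.0 if l1 <= 0.0 else (l1 - ov) / l1
        m2 = 1.0 if l2 <= 0.0 else (l2 - ov) / l2
        acc += 0.5 * (m1 + m2)
    return acc / n


@njit(cache=True)
def delta_energy_arrays(x, types, l0, eps, K, r, i, dx):
    """Incremental energy change of moving vertex ``i`` of row ``r`` by ``dx``."""
    n = types.shape[1]
    s = 1 - r
    ll = x[r, i] - x[r, i - 1]
    lr = x[r, i + 1] - x[r, i]
    d_el = K * (
        (ll + dx - l0[r, i - 1]) ** 2
        - (ll - l0[r, i - 1]) ** 2
        + (lr - dx - l0[r, i]) ** 2
        - (lr - l0[r, i]) ** 2
    )
    t_left = types[r, i - 1]
    t_right = types[r, i]
    if t_left == t_right or dx == 0.0:
        return d_el
    if dx > 0.0:
        a = x[r, i]
        b = x[r, i] + dx
        t_new, t_old = t_left, t_right
    else:
        a = x[r, i] + dx
        b = x[r, i]
        t_new, t_old = t_right, t_left
    j = np.searchsorted(x[s], a, side="right") - 1
    if j < 0:
        j = 0
    if j > n - 1:
        j = n - 1
    d_adh = 0.0
    lo = a
    while lo < b:
        hi = x[s, j + 1]
        if hi > b:
            hi = b
        if hi > lo:
            t_opp = types[s, j]
            d_adh -= (eps[t_new, t_opp] - eps[t_old, t_opp]) * (hi - lo)
        lo = hi
        if hi >= b or j >= n - 1:
            break
        j += 1
    return d_el + d_adh


@njit(cache=True)
def run_mcmc(x, types, l0, eps, K, E0, deltaX, n_steps, record_every, g,
             rec_mismatch, rec_energy, rec_start, E_current,
             rec_x, record_positions):
    """Run ``n_steps`` Metropolis proposals, recording every ``record_every``.

    A proposal picks one of the 2(N-1) interior vertices uniformly, draws a
    Gaussian displacement of std ``deltaX``, rejects moves that would flip a
    cell past its neighbour, and otherwise accepts with probability
    ``min(1, exp(-dE/E0))``.  When ``record_positions`` is true the full
    vertex array is also snapshotted into ``rec_x`` at each record point.
    Returns (accepted count, records written, running total energy).
    """
    n = types.shape[1]
    n_interior = 2 * (n - 1)
    n_acc = 0
    k = rec_start
    for step in range(n_steps):
        idx = int(g.random() * n_interior)
        if idx >= n_interior:
            idx = n_interior - 1
        r = idx // (n - 1)
        i = idx % (n - 1) + 1
        dx = g.standard_normal() * deltaX
        allowed = True
        if dx > 0.0:
            if dx > x[r, i + 1] - x[r, i]:
                allowed = False
        elif dx < 0.0:
            if -dx > x[r, i] - x[r, i - 1]:
                allowed = False
        if allowed:
            dE = delta_energy_arrays(x, types, l0, eps, K, r, i, dx)
            accept = dE <= 0.0
            if not accept:
                accept = g.random() < np.exp(-dE / E0)
            if accept:
                x[r, i] += dx
                E_current += dE
                n_acc += 1
        if (step + 1) % record_every == 0:
            rec_mismatch[k] = tissue_mismatch_arrays(x)
            rec_energy[k] = E_current
            if record_positions:
                for rr in range(2):
                    for ii in range(x.shape[1]):
                        rec_x[k, rr, ii] = x[rr, ii]
            k += 1
    return n_acc, k - rec_start, E_current


@njit(cache=True)
def run_dynamics_kernel(x, types, l0, tension, Kc, xi, dt, n_steps,
                        record_every, rec_mismatch, rec_start, length_floor):
    """Synchronous explicit-Euler integration of the overdamped vertex model.

    Force on an interior vertex: tension of the interface segment just right
    of it minus the segment just left (each typed by the flanking own-row
    cell and the opposing cell at that side), plus the log-elastic terms
    K*log(L_right/L0_right) - K*log(L_left/L0_left).  Displacements are
    clamped to half the adjacent gap minus half the length floor, which
    guarantees cell ordering; clamp events are counted and returned.
    """
    n = types.shape[1]
    dxbuf = np.zeros((2, n + 1))
    k = rec_start
    n_clamped = 0
    for step in range(n_steps):
        for r in range(2):
            s = 1 - r
            for i in range(1, n):
                pos = x[r, i]
                ll = pos - x[r, i - 1]
                lr = x[r, i + 1] - pos
                f = Kc[r, i] * np.log(lr / l0[r, i]) - Kc[r, i - 1] * np.log(
                    ll / l0[r, i - 1]
                )
                jr = np.searchsorted(x[s], pos, side="right") - 1
                if jr < 0:
                    jr = 0
                if jr > n - 1:
                    jr = n - 1
                jl = np.searchsorted(x[s], pos, side="left") - 1
                if jl < 0:
                    jl = 0
                if jl > n - 1:
                    jl = n - 1
                f += tension[types[r, i], types[s, jr]] - tension[
                    types[r, i - 1], types[s, jl]
                ]
                dx = dt / xi * f
                max_r = 0.5 * (lr - length_floor)
                max_l = 0.5 * (ll - length_floor)
                if max_r < 0.0:
                    max_r = 0.0
                if max_l < 0.0:
                    max_l = 0.0
                if dx > max_r:
                    dx = max_r
                    n_clamped += 1
                elif dx < -max_l:
                    dx = -max_l
                    n_clamped += 1
                dxbuf[r, i] = dx
        for r in range(2):
            for i in range(1, n):
                x[r, i] += dxbuf[r, i]
        if (step + 1) % record_every == 0:
            rec_mismatch[k] = tissue_mismatch_arrays(x)
            k += 1
    return k - rec_start, n_clamped
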