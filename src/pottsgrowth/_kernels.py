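"""Numba kernels for the lattice layer.

Everything here operates on plain arrays so it can be jitted; the
user-facing surface lives in :mod:`pottsgrowth.engine`.  Randomness uses
an explicit splitmix64 state passed in as a one-element ``uint64`` array,
which keeps runs bit-reproducible for a given seed independent of numba
version or threading.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Moore neighborhood offsets, in cyclic (ring) order around the center.
_MOORE = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)],
    dtype=np.int64,
)

_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_MUL1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_MUL2 = np.uint64(0x94D049BB133111EB)


@njit(cache=True, inline="always")
def _next_u64(state):
    state[0] = state[0] + _SM_GAMMA
    z = state[0]
    z = (z ^ (z >> np.uint64(30))) * _SM_MUL1
    z = (z ^ (z >> np.uint64(27))) * _SM_MUL2
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _rand_unit(state):
    # 53-bit mantissa uniform in [0, 1)
    return (_next_u64(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _rand_below(state, n):
    return int(_rand_unit(state) * n)


@njit(cache=True, inline="always")
def _pair_j(a, b, Jcc, Jcm):
    """Interfacial energy of one unordered neighbor site pair."""
    if a == b:
        return 0.0
    if a > 0 and b > 0:
        return Jcc
    return Jcm


@njit(cache=True)
def delta_energy(spin, r, c, s_new, area, target, Jcc, Jcm, lam):
    """Energy change of copying identity ``s_new`` onto site ``(r, c)``.

    Interfacial term over the 8-neighborhood (out-of-box sites count as
    immutable medium: the confinement wall interacts via Jcm) plus the
    elastic terms of the losing and gaining cells.
    """
    side = spin.shape[0]
    s_old = spin[r, c]
    d_int = 0.0
    for m in range(8):
        rn = r + _MOORE[m, 0]
        cn = c + _MOORE[m, 1]
        if 0 <= rn < side and 0 <= cn < side:
            sn = spin[rn, cn]
        else:
            sn = 0
        d_int += _pair_j(s_new, sn, Jcc, Jcm) - _pair_j(s_old, sn, Jcc, Jcm)
    d_el = 0.0
    if s_old > 0:
        a = float(area[s_old])
        t = target[s_old]
        d_el += lam * ((a - 1.0 - t) ** 2 - (a - t) ** 2)
    if s_new > 0:
        a = float(area[s_new])
        t = target[s_new]
        d_el += lam * ((a + 1.0 - t) ** 2 - (a - t) ** 2)
    return d_int + d_el


@njit(cache=True)
def local_connectivity_ok(spin, r, c, cid):
    """True iff removing ``(r, c)`` from cell ``cid`` keeps its remaining
    sites in the Moore neighborhood a single 8-connected component.

    A conservative local test: copies that would fragment the losing cell
    are rejected outright.  Zero remaining neighbors (the cell's last
    site) passes vacuously.
    """
    side = spin.shape[0]
    member = np.zeros(8, dtype=np.uint8)
    n_mem = 0
    for m in range(8):
        rn = r + _MOORE[m, 0]
        cn = c + _MOORE[m, 1]
        if 0 <= rn < side and 0 <= cn < side and spin[rn, cn] == cid:
            member[m] = 1
            n_mem += 1
    if n_mem <= 1:
        return True
    # flood fill over member positions, adjacency = 8-adjacency between
    # the neighborhood sites themselves (center excluded)
    visited = np.zeros(8, dtype=np.uint8)
    stack = np.empty(8, dtype=np.int64)
    top = 0
    for m in range(8):
        if member[m] == 1:
            stack[top] = m
            top += 1
            visited[m] = 1
            break
    reached = 1
    while top > 0:
        top -= 1
        i = stack[top]
        for j in range(8):
            if member[j] == 1 and visited[j] == 0:
                dr = _MOORE[i, 0] - _MOORE[j, 0]
                dc = _MOORE[i, 1] - _MOORE[j, 1]
                if -1 <= dr <= 1 and -1 <= dc <= 1:
                    visited[j] = 1
                    stack[top] = j
                    top += 1
                    reached += 1
    return reached == n_mem


@njit(cache=True)
def run_mcs_kernel(
    spin, area, target, fragile, Jcc, Jcm, lam, kBT, state, n_attempts
):
    """One Monte Carlo step: ``n_attempts`` random copy attempts.

    Returns (accepted count, summed energy change of accepted moves).
    Cell areas are maintained incrementally in ``area``.  ``fragile`` is
    a per-id uint8 flag: cells marked fragile (apoptotic, draining to
    zero) are exempt from the connectivity constraint — dying cells may
    fragment, which keeps topologically stuck remnants from freezing.
    """
    side = spin.shape[0]
    accepted = 0
    de_sum = 0.0
    for _ in range(n_attempts):
        r = _rand_below(state, side)
        c = _rand_below(state, side)
        m = _rand_below(state, 8)
        rs = r + _MOORE[m, 0]
        cs = c + _MOORE[m, 1]
        if rs < 0 or rs >= side or cs < 0 or cs >= side:
            continue  # the wall is immutable and never a copy source
        s_new = spin[rs, cs]
        s_old = spin[r, c]
        if s_new == s_old:
            continue
        if (
            s_old > 0
            and fragile[s_old] == 0
            and not local_connectivity_ok(spin, r, c, s_old)
        ):
            continue
        dE = delta_energy(spin, r, c, s_new, area, target, Jcc, Jcm, lam)
        if dE <= 0.0 or _rand_unit(state) < np.exp(-dE / kBT):
            spin[r, c] = s_new
            if s_old > 0:
                area[s_old] -= 1
            if s_new > 0:
                area[s_new] += 1
            accepted += 1
            de_sum += dE
    return accepted, de_sum
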