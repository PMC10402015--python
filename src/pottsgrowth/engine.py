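"""The physical layer: lattice state, mechanical energy, Metropolis dynamics.

Cells are sets of lattice sites sharing a positive integer identity
(spin); identity 0 is the external medium.  The mechanical energy is

    E = sum_{neighbor pairs i,j, n_i != n_j} J(tau_i, tau_j)
        + lambda * sum_cells (A - A_T)^2

with interfacial pairs taken over the 8-neighbor (Moore) neighborhood and
each unordered pair counted once.  Dynamics proceed by Metropolis
identity-copy attempts between adjacent sites; one Monte Carlo step (MCS)
is side^2 attempts and is the simulation's unit of time.  Sites outside
the square confinement are immutable medium interacting via Jcm.

Copies that would locally fragment the losing cell are rejected outright
(cells never split except through division); apoptotic cells draining to
zero are exempt, since their remnants can otherwise anneal into
diagonal-ring configurations that no single-site removal can shrink.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

from . import _kernels
from .params import SimParams

__all__ = [
    "Phase",
    "Tissue",
    "total_energy",
    "delta_energy_copy",
    "metropolis_accept",
    "connectivity_ok",
    "run_mcs",
    "neighbor_topology",
]

#: Offsets whose shifted overlap enumerates every unordered Moore pair once.
_HALF_MOORE = ((0, 1), (1, 0), (1, 1), (1, -1))


class Phase(IntEnum):
    """Cell-cycle phase codes."""

    G1 = 0
    TIMER = 1  # S/G2/M, fixed-duration
    APOPTOTIC = 2


class Tissue:
    """Mutable simulation state: lattice plus per-cell records.

    Per-cell attributes are stored in flat arrays indexed by cell id
    (id 0 is the medium and unused); ``alive`` marks ids currently on the
    lattice.  A single seeded RNG stream (``rng`` for Python-level draws,
    a derived splitmix64 state for the lattice kernel) makes runs with
    identical parameters and seed bit-reproducible.
    """

    _INITIAL_CAPACITY = 64

    def __init__(self, params: SimParams, side: int | None = None):
        self.params = params
        self.side = int(side if side is not None else params.side)
        self.spin = np.zeros((self.side, self.side), dtype=np.int32)
        self.t = 0
        self.rng = np.random.default_rng(params.seed)
        self._kernel_state = np.array(
            [self.rng.integers(0, 2**63, dtype=np.uint64)], dtype=np.uint64
        )
        n = self._INITIAL_CAPACITY
        self.area = np.zeros(n, dtype=np.int64)
        self.target = np.zeros(n, dtype=np.float64)
        self.phase = np.zeros(n, dtype=np.int8)
        self.As_i = np.zeros(n, dtype=np.float64)
        self.tau0_i = np.zeros(n, dtype=np.float64)
        self.clock = np.zeros(n, dtype=np.float64)
        self.birth_t = np.zeros(n, dtype=np.float64)
        self.generation = np.zeros(n, dtype=np.int64)
        self.alive = np.zeros(n, dtype=bool)
        self.next_id = 1
        #: rows (t, event, cell_id, parent_id); events are one of
        #: birth, apoptosis_start, apoptosis_removal, extrusion
        self.events: list[tuple[int, str, int, int]] = []
        #: rows (t, cell_id, area_at_mitosis, birth_t, generation)
        self.division_records: list[tuple[int, int, int, float, int]] = []

    # -- cell bookkeeping -------------------------------------------------

    def _ensure_capacity(self, cid: int) -> None:
        n = len(self.area)
        if cid < n:
            return
        new = max(2 * n, cid + 1)
        for name in (
            "area",
            "target",
            "phase",
            "As_i",
            "tau0_i",
            "clock",
            "birth_t",
            "generation",
            "alive",
        ):
            old = getattr(self, name)
            grown = np.zeros(new, dtype=old.dtype)
            grown[:n] = old
            setattr(self, name, grown)

    def new_cell_id(self) -> int:
        cid = self.next_id
        self.next_id += 1
        self._ensure_capacity(cid)
        return cid

    def live_ids(self) -> np.ndarray:
        return np.flatnonzero(self.alive)

    @property
    def n_cells(self) -> int:
        return int(self.alive.sum())

    def colony_area(self) -> int:
        """Total number of cell-occupied sites."""
        return int(self.area[self.alive].sum())

    def cell_sites(self, cid: int) -> np.ndarray:
        """(n, 2) array of (row, col) sites owned by cell ``cid``."""
        return np.argwhere(self.spin == cid)

    def centroids(self) -> dict[int, tuple[float, float]]:
        """Centroid (row, col) of every live cell, from the lattice."""
        flat = self.spin.ravel()
        n = self.next_id
        counts = np.bincount(flat, minlength=n).astype(float)
        rows = np.repeat(np.arange(self.side), self.side)
        cols = np.tile(np.arange(self.side), self.side)
        rsum = np.bincount(flat, weights=rows, minlength=n)
        csum = np.bincount(flat, weights=cols, minlength=n)
        out = {}
        for cid in self.live_ids():
            if counts[cid] > 0:
                out[int(cid)] = (rsum[cid] / counts[cid], csum[cid] / counts[cid])
        return out

    def recount_areas(self) -> np.ndarray:
        """Recompute all cell areas from the lattice (for verification)."""
        return np.bincount(self.spin.ravel(), minlength=len(self.area)).astype(np.int64)

    def log_event(self, event: str, cid: int, parent: int = 0) -> None:
        self.events.append((self.t, event, int(cid), int(parent)))


# -- physical-layer operations -------------------------------------------


def _shifted_views(pad: np.ndarray, dr: int, dc: int):
    """Aligned array views such that a[i] and b[i] are (dr, dc)-neighbors."""
    a, b = pad, pad
    if dr > 0:
        a, b = a[:-dr, :], b[dr:, :]
    if dc > 0:
        a, b = a[:, :-dc], b[:, dc:]
    elif dc < 0:
        a, b = a[:, -dc:], b[:, :dc]
    return a, b


def total_energy(tissue: Tissue, params: SimParams | None = None) -> float:
    """Full mechanical energy of the current state (vectorized).

    Interfacial pairs over the Moore neighborhood, each unordered pair
    once, including pairs with the immutable medium wall outside the box;
    plus the area-elastic term of every live cell.
    """
    p = params or tissue.params
    pad = np.pad(tissue.spin, 1)  # wall = medium
    e_int = 0.0
    for dr, dc in _HALF_MOORE:
        a, b = _shifted_views(pad, dr, dc)
        diff = a != b
        both_cell = (a > 0) & (b > 0)
        e_int += p.Jcc * np.count_nonzero(diff & both_cell)
        e_int += p.Jcm * np.count_nonzero(diff & ~both_cell)
    live = tissue.alive
    dev = tissue.area[live].astype(float) - tissue.target[live]
    return float(e_int + p.lam * np.sum(dev**2))


def delta_energy_copy(
    tissue: Tissue, target_site: tuple[int, int], source_site: tuple[int, int]
) -> float:
    """Energy change of copying the source site's identity onto the target.

    Computed from local terms only; equals the difference of
    :func:`total_energy` before and after the copy.
    """
    r, c = target_site
    rs, cs = source_site
    if max(abs(r - rs), abs(c - cs)) != 1:
        raise ValueError("source must be a Moore neighbor of the target site")
    s_new = int(tissue.spin[rs, cs])
    if s_new == int(tissue.spin[r, c]):
        raise ValueError("copy between equal identities is never proposed")
    p = tissue.params
    return float(
        _kernels.delta_energy(
            tissue.spin, r, c, s_new, tissue.area, tissue.target, p.Jcc, p.Jcm, p.lam
        )
    )


def metropolis_accept(dE: float, kBT: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept always if dE <= 0, else with exp(-dE/kBT)."""
    if not kBT > 0:
        raise ValueError("kBT must be strictly positive")
    if dE <= 0:
        return True
    return bool(rng.random() < np.exp(-dE / kBT))


def connectivity_ok(tissue_or_spin, site: tuple[int, int], losing_id: int) -> bool:
    """True iff removing ``site`` keeps the losing cell locally connected."""
    if losing_id <= 0:
        raise ValueError("losing_id must be a positive cell id")
    spin = tissue_or_spin.spin if isinstance(tissue_or_spin, Tissue) else tissue_or_spin
    return bool(_kernels.local_connectivity_ok(spin, site[0], site[1], losing_id))


def run_mcs(tissue: Tissue, n_attempts: int | None = None) -> tuple[int, float]:
    """Advance the lattice by one Monte Carlo step (side^2 copy attempts).

    Returns the number of accepted moves and the summed energy change of
    accepted moves (so that E_before + de_sum == E_after).  Does not
    advance the decision layer or the clock; see
    :func:`pottsgrowth.simulate.run_simulation` for the full loop.
    """
    p = tissue.params
    n = n_attempts if n_attempts is not None else tissue.side * tissue.side
    fragile = (tissue.phase == Phase.APOPTOTIC).astype(np.uint8)
    accepted, de_sum = _kernels.run_mcs_kernel(
        tissue.spin,
        tissue.area,
        tissue.target,
        fragile,
        p.Jcc,
        p.Jcm,
        p.lam,
        p.kBT,
        tissue._kernel_state,
        n,
    )
    return int(accepted), float(de_sum)


def neighbor_topology(tissue: Tissue):
    """Cell adjacency from the lattice.

    Returns ``(pairs, medium_contact)`` where ``pairs`` is an (m, 2) array
    of cell-id pairs sharing at least one Moore interfacial site pair and
    ``medium_contact`` is a boolean array (indexed by id) marking cells
    with at least one cell-medium interfacial pair (boundary cells,
    including contact with the confinement wall).
    """
    pad = np.pad(tissue.spin, 1)
    pair_list = []
    medium_contact = np.zeros(len(tissue.area), dtype=bool)
    for dr, dc in _HALF_MOORE:
        a, b = _shifted_views(pad, dr, dc)
        diff = a != b
        cc = diff & (a > 0) & (b > 0)
        if cc.any():
            pair_list.append(np.stack([a[cc], b[cc]], axis=1))
        cm = diff & ((a > 0) ^ (b > 0))
        if cm.any():
            touching = np.where(a[cm] > 0, a[cm], b[cm])
            medium_contact[touching] = True
    if pair_list:
        raw = np.concatenate(pair_list).astype(np.int64)
        lo = np.minimum(raw[:, 0], raw[:, 1])
        hi = np.maximum(raw[:, 0], raw[:, 1])
        # encode unordered pairs as scalars for a fast 1-D unique
        codes = np.unique(lo * np.int64(len(tissue.area)) + hi)
        pairs = np.stack(
            [codes // len(tissue.area), codes % len(tissue.area)], axis=1
        )
    else:
        pairs = np.empty((0, 2), dtype=np.int64)
    return pairs, medium_contact
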