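"""Deterministic small lattice states for tests and examples."""

from __future__ import annotations

import numpy as np

from .engine import Phase, Tissue
from .params import SimParams

__all__ = ["fixture_params", "make_fixture", "tissue_from_spin"]

_KINDS = ("single_cell", "two_cell", "ring", "random_tissue")


def fixture_params(box_area: float, seed: int = 0, **overrides) -> SimParams:
    """Simple round-number parameters for hand-checkable fixtures."""
    defaults = dict(
        kBT=1.0,
        Jcc=1.0,
        Jcm=2.0,
        lam=1.0,
        G=1.0,
        k=0.01,
        tau0_mean=10.0,
        tau0_sd=1.0,
        As_mean=30.0,
        As_sd=3.0,
        papo_max=0.01,
        rho_half=0.05,
        alpha=30.0,
        box_area=box_area,
        seed=seed,
        t_max=100,
    )
    defaults.update(overrides)
    return SimParams(**defaults)


def tissue_from_spin(spin: np.ndarray, params: SimParams, targets=None) -> Tissue:
    """Wrap an explicit spin array into a consistent Tissue.

    Every positive identity becomes a live G1 cell with target area equal
    to its area unless ``targets`` (a {id: target} mapping) overrides it.
    """
    spin = np.asarray(spin, dtype=np.int32)
    if spin.shape[0] != spin.shape[1]:
        raise ValueError("lattice must be square")
    tissue = Tissue(params, side=spin.shape[0])
    tissue.spin[...] = spin
    ids = np.unique(spin)
    ids = ids[ids > 0]
    for cid in ids:
        cid = int(cid)
        while tissue.next_id <= cid:
            tissue.new_cell_id()
        n = int(np.count_nonzero(spin == cid))
        tissue.area[cid] = n
        tissue.target[cid] = float(targets[cid]) if targets and cid in targets else float(n)
        tissue.phase[cid] = Phase.G1
        tissue.As_i[cid] = params.As_mean
        tissue.tau0_i[cid] = params.tau0_mean
        tissue.alive[cid] = True
        tissue.log_event("birth", cid, parent=0)
    return tissue


def make_fixture(kind: str, size: int, seed: int = 0, params: SimParams | None = None) -> Tissue:
    """Deterministic small states (side <= 40) with hand-checkable geometry.

    - ``single_cell``: one square block cell centered on the lattice.
    - ``two_cell``: two side-by-side rectangles sharing one straight
      interface.
    - ``ring``: a 3 x 3 block arrangement (one interior cell surrounded
      by eight boundary cells).
    - ``random_tissue``: a lattice Voronoi tessellation of seeded points
      (cells are connected by construction), with a medium margin.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {_KINDS}")
    if not 4 <= size <= 40:
        raise ValueError("fixture size must be between 4 and 40 sites")
    p = params or fixture_params(box_area=float(size * size), seed=seed)
    spin = np.zeros((size, size), dtype=np.int32)
    rng = np.random.default_rng(seed)
    if kind == "single_cell":
        s = max(size // 3, 2)
        lo = (size - s) // 2
        spin[lo : lo + s, lo : lo + s] = 1
    elif kind == "two_cell":
        s = max(size // 3, 2)
        r0 = (size - s) // 2
        c0 = (size - 2 * s) // 2
        spin[r0 : r0 + s, c0 : c0 + s] = 1
        spin[r0 : r0 + s, c0 + s : c0 + 2 * s] = 2
    elif kind == "ring":
        s = max(size // 4, 2)
        off = (size - 3 * s) // 2
        cid = 0
        for i in range(3):
            for j in range(3):
                cid += 1
                spin[
                    off + i * s : off + (i + 1) * s, off + j * s : off + (j + 1) * s
                ] = cid
    else:  # random_tissue
        margin = max(size // 8, 1)
        n_cells = max((size - 2 * margin) ** 2 // 25, 2)
        pts = rng.uniform(margin, size - margin, size=(n_cells, 2))
        rows, cols = np.indices((size, size))
        interior = (
            (rows >= margin)
            & (rows < size - margin)
            & (cols >= margin)
            & (cols < size - margin)
        )
        d2 = (rows[..., None] - pts[:, 0]) ** 2 + (cols[..., None] - pts[:, 1]) ** 2
        spin[interior] = np.argmin(d2, axis=-1)[interior] + 1
        # relabel to drop empty ids
        ids = np.unique(spin)
        remap = np.zeros(ids.max() + 1, dtype=np.int32)
        remap[ids[ids > 0]] = np.arange(1, np.count_nonzero(ids > 0) + 1)
        spin = remap[spin]
    tissue = tissue_from_spin(spin, p)
    if kind == "random_tissue":
        # detune targets from areas so the elastic term is active
        live = tissue.live_ids()
        tissue.target[live] = np.maximum(
            tissue.target[live] + rng.normal(0.0, 3.0, len(live)), 1.0
        )
    return tissue
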