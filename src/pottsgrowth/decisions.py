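"""Cell-autonomous rules: growth, G1-sizer/timer cycle, apoptosis, extrusion.

The decision layer ticks once per MCS, after the lattice update, in a
fixed order (see :func:`step_decision_layer`).  Cells grow by increasing
their *target* area at a crowding-suppressed rate

    dA_T/dt = G * exp(-k * (A - A_T)^2),

stay in G1 until their actual area exceeds an individually drawn sizer
threshold ``As_i``, then spend a fixed (individually drawn) time
``tau0_i`` in S/G2/M before dividing.  Apoptosis is sampled per cell per
MCS with a sigmoidal probability of the local density; an apoptotic
cell's target area is set to zero and it drains away through the lattice
dynamics.  Cells whose area falls below a quarter of the mean live-cell
area are extruded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .engine import Phase, Tissue, neighbor_topology
from .params import AREA_FLOOR, TIME_FLOOR, TRUNC_SD, SimParams

__all__ = [
    "CellState",
    "grow_target_area",
    "check_g1s_transition",
    "advance_timer",
    "divide_cell",
    "local_density",
    "apoptosis_probability",
    "trigger_apoptosis",
    "check_extrusion",
    "remove_cell",
    "step_decision_layer",
    "seed_tissue",
    "draw_threshold",
]


@dataclass
class CellState:
    """Snapshot of one cell's decision-layer state."""

    id: int
    phase: Phase
    area: int
    target_area: float
    As_i: float
    tau0_i: float
    timer_clock: float
    birth_time: float
    generation: int


def cell_state(tissue: Tissue, cid: int) -> CellState:
    """Extract a :class:`CellState` view of cell ``cid``."""
    return CellState(
        id=cid,
        phase=Phase(int(tissue.phase[cid])),
        area=int(tissue.area[cid]),
        target_area=float(tissue.target[cid]),
        As_i=float(tissue.As_i[cid]),
        tau0_i=float(tissue.tau0_i[cid]),
        timer_clock=float(tissue.clock[cid]),
        birth_time=float(tissue.birth_t[cid]),
        generation=int(tissue.generation[cid]),
    )


def draw_threshold(
    rng: np.random.Generator, mean: float, sd: float, floor: float
) -> float:
    """Gaussian draw truncated at +/- 3 SD and floored to stay physical."""
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= TRUNC_SD * sd or sd == 0:
            return max(x, floor)


# -- single-cell rules (scalar forms) -------------------------------------


def grow_target_area(cell: CellState, area: float, p: SimParams, dt: float = 1.0) -> float:
    """Updated target area after one growth step of duration ``dt``."""
    if cell.phase is Phase.APOPTOTIC:
        raise ValueError("apoptotic cells do not grow")
    return cell.target_area + dt * p.G * np.exp(-p.k * (area - cell.target_area) ** 2)

def check_g1s_transition(cell: CellState, area: float) -> Phase:
    """G1 -> TIMER when the actual area strictly exceeds the sizer draw."""
    if cell.phase is not Phase.G1:
        raise ValueError("sizer check applies only to G1 cells")
    return Phase.TIMER if area > cell.As_i else Phase.G1


def advance_timer(cell: CellState, dt: float = 1.0) -> bool:
    """Advance the S/G2/M clock; True when the cell is due to divide."""
    if cell.phase is not Phase.TIMER:
        raise ValueError("timer applies only to S/G2/M cells")
    cell.timer_clock += dt
    return cell.timer_clock >= cell.tau0_i


def local_density(cell_area: float, neighbor_areas) -> float:
    """Sum of inverse areas of a cell and its touching neighbors [1/area]."""
    areas = np.concatenate([[cell_area], np.asarray(neighbor_areas, dtype=float)])
    if np.any(areas <= 0):
        raise ValueError("zero-area cell in a density sum: inconsistent state")
    return float(np.sum(1.0 / areas))


def apoptosis_probability(rho, p: SimParams):
    """Sigmoidal apoptosis probability per decision step.

    p(rho) = papo_max / (1 + exp(-alpha * (rho - rho_half))); monotone
    increasing and bounded in (0, papo_max).
    """
    return p.papo_max / (1.0 + np.exp(-p.alpha * (np.asarray(rho, float) - p.rho_half)))


def check_extrusion(area: float, mean_area: float) -> bool:
    """Strict quarter-of-mean rule: extrude iff area < mean_area / 4."""
    return area < mean_area / 4.0


def trigger_apoptosis(tissue: Tissue, cid: int, rho: float) -> bool:
    """Sample the apoptosis decision for one cell; True if it triggered."""
    p = tissue.params
    if not p.apoptosis_enabled:
        return False
    if tissue.phase[cid] == Phase.APOPTOTIC:
        raise ValueError("cell is already apoptotic")
    if tissue.rng.random() < float(apoptosis_probability(rho, p)):
        _start_apoptosis(tissue, cid)
        return True
    return False


def _start_apoptosis(tissue: Tissue, cid: int) -> None:
    tissue.phase[cid] = Phase.APOPTOTIC
    tissue.target[cid] = 0.0
    tissue.log_event("apoptosis_start", cid)


def remove_cell(tissue: Tissue, cid: int, reason: str) -> None:
    """Retire a cell: its remaining sites become medium; event logged.

    ``reason`` is 'apoptosis_removal' (an apoptotic cell drained to zero
    or fell below the extrusion threshold) or 'extrusion' (a live cell).
    """
    if reason not in ("apoptosis_removal", "extrusion"):
        raise ValueError(f"unknown removal reason {reason!r}")
    if tissue.area[cid] > 0:
        tissue.spin[tissue.spin == cid] = 0
        tissue.area[cid] = 0
    tissue.alive[cid] = False
    tissue.log_event(reason, cid)


# -- division --------------------------------------------------------------


def _principal_axis(rel: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Long axis of a site cloud; random direction when degenerate."""
    cov = rel.T @ rel / len(rel)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] - evals[0] < 1e-12:  # isotropic: orientation is a tie
        theta = rng.uniform(0.0, np.pi)
        return np.array([np.cos(theta), np.sin(theta)])
    return evecs[:, -1]


def _split_sites(
    sites: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Partition a connected site set into two connected halves.

    The cut is a straight line through the centroid perpendicular to the
    cell's long axis (principal axis of the site second moment); sites on
    the line are assigned at random.  Fragments created by the cut on
    either side are reattached to whichever daughter they touch.
    """
    centroid = sites.mean(axis=0)
    rel = sites - centroid
    axis = _principal_axis(rel, rng)
    proj = rel @ axis
    side_a = proj > 1e-9
    side_b = proj < -1e-9
    ties = ~(side_a | side_b)
    if ties.any():
        flip = rng.random(int(ties.sum())) < 0.5
        idx = np.flatnonzero(ties)
        side_a[idx[flip]] = True
        side_b[idx[~flip]] = True
    if not side_a.any() or not side_b.any():
        # degenerate cut: split at the median projection instead
        order = np.argsort(proj, kind="stable")
        half = len(sites) // 2
        side_a = np.zeros(len(sites), dtype=bool)
        side_a[order[half:]] = True
        side_b = ~side_a
    return _repair_split(sites, side_a, rng)


def _repair_split(sites, side_a, rng):
    """Keep each daughter 8-connected, reattaching stray fragments."""
    rmin, cmin = sites.min(axis=0)
    shape = tuple(sites.max(axis=0) - (rmin, cmin) + 1)
    local = sites - (rmin, cmin)
    struct = np.ones((3, 3), dtype=bool)

    def main_component(mask_flags):
        img = np.zeros(shape, dtype=bool)
        img[local[mask_flags, 0], local[mask_flags, 1]] = True
        lab, n = ndimage.label(img, structure=struct)
        if n <= 1:
            return mask_flags
        sizes = ndimage.sum_labels(img, lab, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        out = mask_flags.copy()
        out[mask_flags] = lab[local[mask_flags, 0], local[mask_flags, 1]] == keep
        return out

    a = main_component(side_a)
    b = main_component(~side_a)
    unassigned = ~(a | b)
    # attach leftovers to whichever daughter they touch, iterating until done
    img_a = np.zeros(shape, dtype=bool)
    img_a[local[a, 0], local[a, 1]] = True
    img_b = np.zeros(shape, dtype=bool)
    img_b[local[b, 0], local[b, 1]] = True
    while unassigned.any():
        progressed = False
        for i in np.flatnonzero(unassigned):
            r, c = local[i]
            r0, r1 = max(r - 1, 0), min(r + 2, shape[0])
            c0, c1 = max(c - 1, 0), min(c + 2, shape[1])
            touch_a = img_a[r0:r1, c0:c1].any()
            touch_b = img_b[r0:r1, c0:c1].any()
            if touch_a or touch_b:
                if touch_a and touch_b:
                    pick_a = bool(rng.random() < 0.5)
                else:
                    pick_a = touch_a
                (img_a if pick_a else img_b)[r, c] = True
                (a if pick_a else b)[i] = True
                unassigned[i] = False
                progressed = True
        if not progressed:  # isolated fragment: give it to the smaller side
            i = int(np.flatnonzero(unassigned)[0])
            pick_a = a.sum() <= b.sum()
            (img_a if pick_a else img_b)[local[i, 0], local[i, 1]] = True
            (a if pick_a else b)[i] = True
            unassigned[i] = False
    return sites[a], sites[b]


def divide_cell(tissue: Tissue, cid: int) -> tuple[int, int]:
    """Split a due cell into two daughters; returns the daughter ids.

    The mother's sites are partitioned by a straight cut through the
    centroid perpendicular to her long axis.  Each daughter receives a
    new unique id, starts in G1 with target area equal to its own
    post-split area, fresh Gaussian draws of the sizer and timer
    thresholds, and generation incremented; each daughter is logged as a
    birth with the mother as parent.
    """
    sites = tissue.cell_sites(cid)
    if len(sites) < 2:
        raise ValueError("cells of fewer than 2 sites cannot divide")
    p = tissue.params
    tissue.division_records.append(
        (
            tissue.t,
            int(cid),
            int(tissue.area[cid]),
            float(tissue.birth_t[cid]),
            int(tissue.generation[cid]),
        )
    )
    halves = _split_sites(sites, tissue.rng)
    gen = int(tissue.generation[cid]) + 1
    tissue.alive[cid] = False
    tissue.area[cid] = 0
    daughters = []
    for half in halves:
        did = tissue.new_cell_id()
        tissue.spin[half[:, 0], half[:, 1]] = did
        tissue.area[did] = len(half)
        tissue.target[did] = float(len(half))
        tissue.phase[did] = Phase.G1
        tissue.As_i[did] = draw_threshold(tissue.rng, p.As_mean, p.As_sd, AREA_FLOOR)
        tissue.tau0_i[did] = draw_threshold(
            tissue.rng, p.tau0_mean, p.tau0_sd, TIME_FLOOR
        )
        tissue.clock[did] = 0.0
        tissue.birth_t[did] = float(tissue.t)
        tissue.generation[did] = gen
        tissue.alive[did] = True
        tissue.log_event("birth", did, parent=cid)
        daughters.append(did)
    return daughters[0], daughters[1]


# -- the per-MCS decision sweep --------------------------------------------


def local_densities(tissue: Tissue, normalized: bool = False) -> np.ndarray:
    """Local density of every live non-apoptotic cell, indexed by id.

    With ``normalized=False`` (the raw form) this is the sum of inverse
    areas of the cell and its touching neighbors; with
    ``normalized=True`` the sum is divided by the number of cells in the
    neighborhood (cell + neighbors), giving the mean inverse area — a
    true local number density, which is the scale on which the apoptosis
    hazard is calibrated (see docs/methods.md).

    Apoptotic (draining) cells are excluded from the sums: their shrinking
    areas would otherwise contribute divergent inverse-area terms.
    """
    pairs, _ = neighbor_topology(tissue)
    rho = np.zeros(len(tissue.area))
    nbh_count = np.ones(len(tissue.area))
    live = tissue.alive & (tissue.phase != Phase.APOPTOTIC) & (tissue.area > 0)
    inv = np.zeros_like(rho)
    inv[live] = 1.0 / tissue.area[live]
    rho[live] = inv[live]
    if len(pairs):
        u, v = pairs[:, 0], pairs[:, 1]
        ok = live[u] & live[v]
        np.add.at(rho, u[ok], inv[v[ok]])
        np.add.at(rho, v[ok], inv[u[ok]])
        np.add.at(nbh_count, u[ok], 1.0)
        np.add.at(nbh_count, v[ok], 1.0)
    if normalized:
        rho = rho / nbh_count
    return rho


def step_decision_layer(tissue: Tissue) -> None:
    """One decision-layer tick (call once per MCS, after the lattice step).

    Fixed stage order: (1) remove drained apoptotic cells, (2) extrusion,
    (3) apoptosis sampling, (4) target-area growth, (5) G1/S sizer checks,
    (6) timer advance and divisions.  Changing this order is a breaking
    change.
    """
    p = tissue.params
    # (1) drained apoptotic cells (and degenerate zero-area live cells)
    for cid in np.flatnonzero(tissue.alive & (tissue.area == 0)):
        reason = (
            "apoptosis_removal"
            if tissue.phase[cid] == Phase.APOPTOTIC
            else "extrusion"
        )
        remove_cell(tissue, cid, reason)
    # (2) extrusion: strict quarter of the mean non-apoptotic live area
    live = tissue.alive & (tissue.phase != Phase.APOPTOTIC)
    if live.any():
        mean_area = float(tissue.area[live].mean())
        for cid in np.flatnonzero(tissue.alive):
            if check_extrusion(float(tissue.area[cid]), mean_area):
                reason = (
                    "apoptosis_removal"
                    if tissue.phase[cid] == Phase.APOPTOTIC
                    else "extrusion"
                )
                remove_cell(tissue, cid, reason)
    # (3) apoptosis sampling
    live = tissue.alive & (tissue.phase != Phase.APOPTOTIC)
    if p.apoptosis_enabled and live.any():
        ids = np.flatnonzero(live)
        rho = local_densities(tissue, normalized=True)[ids]
        prob = apoptosis_probability(rho, p)
        hits = tissue.rng.random(len(ids)) < prob
        for cid in ids[hits]:
            _start_apoptosis(tissue, cid)
    # (4) crowding-suppressed growth of target areas
    live = tissue.alive & (tissue.phase != Phase.APOPTOTIC)
    if live.any():
        dev = tissue.area[live].astype(float) - tissue.target[live]
        tissue.target[live] += p.G * np.exp(-p.k * dev**2)
    # (5) G1 -> S transition: strict sizer
    g1 = live & (tissue.phase == Phase.G1)
    passing = g1 & (tissue.area > tissue.As_i)
    tissue.phase[passing] = Phase.TIMER
    tissue.clock[passing] = 0.0
    # (6) timer advance (including cells that entered S this step);
    # divisions, deferred while area < 2 sites
    timer = live & (tissue.phase == Phase.TIMER)
    tissue.clock[timer] += 1.0
    due = np.flatnonzero(timer & (tissue.clock >= tissue.tau0_i) & (tissue.area >= 2))
    for cid in due:
        divide_cell(tissue, cid)


def seed_tissue(params: SimParams) -> Tissue:
    """Initial condition: a single centered disk cell below the sizer.

    The founder has area As/2 (rounded), target area equal to its area,
    phase G1, and its own sizer/timer draws.
    """
    tissue = Tissue(params)
    n_sites = max(int(round(params.As_mean / 2)), int(AREA_FLOOR))
    side = tissue.side
    rows, cols = np.indices((side, side))
    d2 = (rows - (side - 1) / 2.0) ** 2 + (cols - (side - 1) / 2.0) ** 2
    order = np.argsort(d2.ravel(), kind="stable")[:n_sites]
    cid = tissue.new_cell_id()
    tissue.spin.ravel()[order] = cid
    tissue.area[cid] = n_sites
    tissue.target[cid] = float(n_sites)
    tissue.phase[cid] = Phase.G1
    tissue.As_i[cid] = draw_threshold(tissue.rng, params.As_mean, params.As_sd, AREA_FLOOR)
    tissue.tau0_i[cid] = draw_threshold(
        tissue.rng, params.tau0_mean, params.tau0_sd, TIME_FLOOR
    )
    tissue.birth_t[cid] = 0.0
    tissue.generation[cid] = 0
    tissue.alive[cid] = True
    tissue.log_event("birth", cid, parent=0)
    return tissue
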