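"""Derived quantities: pressure, rates, profiles, growth timescales.

All quantities are computed from the raw simulation state or its logged
outputs (time series, event log, division records); nothing here feeds
back into the dynamics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .engine import Phase, Tissue, neighbor_topology

__all__ = [
    "cell_pressure",
    "boundary_pressure_gradient",
    "proliferation_rates",
    "measure_tgrowth",
    "detect_homeostasis",
    "radial_profile",
    "growth_rate_map",
    "g1_fraction",
    "cycle_statistics",
    "record_timeseries_row",
]


def cell_pressure(area, target_area, lam):
    """Cell pressure p = -2 * lam * (A - A_T).

    Positive for a compressed cell (area below target), negative for a
    stretched one; the derivative of the elastic energy with respect to
    area, with sign flipped.
    """
    return -2.0 * lam * (np.asarray(area, dtype=float) - target_area)


def boundary_pressure_gradient(tissue: Tissue) -> float:
    """Pressure drop across the colony boundary, in model energy/area units.

    Boundary cells are those with at least one cell-medium interfacial
    site pair; the reference ring is their cell-neighbors that are not
    themselves boundary cells.  Returns mean interior-ring pressure minus
    mean boundary-ring pressure, i.e. positive when the bulk is
    compressed relative to the rim (the state that drives outward colony
    expansion).  If the colony has no interior ring the gradient is 0,
    with a warning.
    """
    pairs, medium_contact = neighbor_topology(tissue)
    live = tissue.alive
    boundary = medium_contact & live
    if not boundary.any():
        raise ValueError("colony has no boundary cell")
    interior_ring = np.zeros_like(boundary)
    if len(pairs):
        u, v = pairs[:, 0], pairs[:, 1]
        sel = boundary[u] & ~boundary[v] & live[v]
        interior_ring[v[sel]] = True
        sel = boundary[v] & ~boundary[u] & live[u]
        interior_ring[u[sel]] = True
    if not interior_ring.any():
        warnings.warn(
            "all cells touch the medium: boundary pressure gradient undefined, "
            "returning 0",
            stacklevel=2,
        )
        return 0.0
    lam = tissue.params.lam
    p_b = cell_pressure(tissue.area[boundary], tissue.target[boundary], lam).mean()
    p_i = cell_pressure(
        tissue.area[interior_ring], tissue.target[interior_ring], lam
    ).mean()
    return float(p_i - p_b)


def proliferation_rates(
    events: pd.DataFrame,
    tau0: float,
    window: float,
    t_grid=None,
) -> pd.DataFrame:
    """Sliding-window division and elimination rates per cell per tau0.

    ``events`` is the event log (columns t, event, cell_id, parent_id).
    A division is counted once (two simultaneous birth rows sharing a
    parent are one event); eliminations are apoptosis removals plus
    extrusions.  Rates are normalized by the mean live cell count in the
    window and expressed per tau0.
    """
    if window < 1:
        raise ValueError("window must be at least 1 MCS")
    ev = events
    births = ev[(ev["event"] == "birth") & (ev["parent_id"] > 0)]
    division_times = births.drop_duplicates(["t", "parent_id"])["t"].to_numpy(float)
    first_birth = ev[(ev["event"] == "birth") & (ev["parent_id"] == 0)]
    removal_times = ev[ev["event"].isin(["apoptosis_removal", "extrusion"])][
        "t"
    ].to_numpy(float)
    t_max = float(ev["t"].max()) if len(ev) else 0.0
    if t_grid is None:
        t_grid = np.arange(window, t_max + 1, max(1.0, window / 4))
    t_grid = np.asarray(t_grid, dtype=float)
    # reconstruct N(t): seeded cells + net divisions - removals
    all_t = np.sort(
        np.concatenate([division_times, removal_times, first_birth["t"].to_numpy(float)])
    )

    def n_at(t):
        n_seed = np.count_nonzero(first_birth["t"].to_numpy(float) <= t)
        return (
            n_seed
            + np.count_nonzero(division_times <= t)
            - np.count_nonzero(removal_times <= t)
        )

    rows = []
    for t in t_grid:
        lo = t - window
        nb = np.count_nonzero((division_times > lo) & (division_times <= t))
        ne = np.count_nonzero((removal_times > lo) & (removal_times <= t))
        # mean N over the window, averaged at event boundaries
        ts = np.concatenate([[lo], all_t[(all_t > lo) & (all_t <= t)], [t]])
        seg = np.diff(ts)
        n_vals = np.array([n_at(x) for x in ts[:-1]])
        n_mean = float(np.sum(seg * n_vals) / (t - lo)) if t > lo else n_at(t)
        if n_mean <= 0:
            rows.append((t, 0.0, 0.0))
            continue
        scale = tau0 / (window * n_mean)
        rows.append((t, nb * scale, ne * scale))
    return pd.DataFrame(rows, columns=["t", "kbirth", "kelim"])


def measure_tgrowth(t, colony_area, box_area: float, frac: float = 0.99):
    """Time for the colony to fill its confinement.

    First crossing of ``colony_area >= frac * box_area``, linearly
    interpolated between samples; None if never reached.
    """
    t = np.asarray(t, dtype=float)
    a = np.asarray(colony_area, dtype=float)
    threshold = frac * box_area
    above = a >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    t0, t1, a0, a1 = t[i - 1], t[i], a[i - 1], a[i]
    if a1 == a0:
        return float(t1)
    return float(t0 + (threshold - a0) * (t1 - t0) / (a1 - a0))


def detect_homeostasis(
    timeseries: pd.DataFrame,
    tau0: float,
    tol: float = 0.02,
    hold: float | None = None,
    smooth: float | None = None,
):
    """Earliest onset of a joint plateau of cell count and mean density.

    The count and density series are smoothed with a rolling mean of
    width ``smooth`` (default tau0), then the onset is the earliest time
    t* such that both smoothed series stay within relative tolerance
    ``tol`` of their value at t* for at least ``hold`` (default 5 tau0).
    Returns None if no such plateau exists within the series.
    """
    hold = 5 * tau0 if hold is None else hold
    smooth = tau0 if smooth is None else smooth
    ts = timeseries.sort_values("t").reset_index(drop=True)
    t = ts["t"].to_numpy(float)
    if len(t) < 2:
        return None
    dt = np.median(np.diff(t))
    w = max(int(round(smooth / dt)), 1)
    sig = []
    for col in ("n_cells", "mean_density"):
        s = ts[col].rolling(w, min_periods=1, center=True).mean().to_numpy()
        sig.append(s)
    for i in range(len(t)):
        if t[-1] - t[i] < hold:
            break
        j = int(np.searchsorted(t, t[i] + hold, side="right"))
        ok = True
        for s in sig:
            ref = s[i]
            if ref == 0 or np.max(np.abs(s[i:j] - ref)) > tol * abs(ref):
                ok = False
                break
        if ok:
            return float(t[i])
    return None


def radial_profile(tissue: Tissue, n_bins: int = 8) -> pd.DataFrame:
    """Spatially averaged cell area vs distance from the colony center.

    The center is the area-weighted centroid of all cell sites; each live
    cell is assigned to one bin by its centroid distance.  Returns a
    frame (bin_center, mean_area, n_cells); empty bins carry NaN.
    """
    cents = tissue.centroids()
    if not cents:
        raise ValueError("no live cells")
    ids = np.array(sorted(cents))
    xy = np.array([cents[i] for i in ids])
    areas = tissue.area[ids].astype(float)
    center = (xy * areas[:, None]).sum(axis=0) / areas.sum()
    dist = np.hypot(*(xy - center).T)
    edges = np.linspace(0.0, max(dist.max(), 1e-9), n_bins + 1)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        rows.append(
            (
                0.5 * (edges[b] + edges[b + 1]),
                float(areas[sel].mean()) if sel.any() else np.nan,
                int(sel.sum()),
            )
        )
    return pd.DataFrame(rows, columns=["bin_center", "mean_area", "n_cells"])


def growth_rate_map(
    areas_t0: dict[int, float], areas_t1: dict[int, float], delta: float
) -> dict[int, float]:
    """Per-cell area growth rate between two snapshots a time ``delta`` apart.

    Only cells present in both snapshots are reported; negative rates
    (bulk contraction) are allowed.
    """
    if delta <= 0:
        raise ValueError("snapshot separation must be positive")
    common = set(areas_t0) & set(areas_t1)
    return {cid: (areas_t1[cid] - areas_t0[cid]) / delta for cid in common}


def g1_fraction(tissue: Tissue) -> float:
    """Fraction of live non-apoptotic cells currently in G1."""
    live = tissue.alive & (tissue.phase != Phase.APOPTOTIC)
    n = int(live.sum())
    if n == 0:
        raise ValueError("no live cells")
    return float(np.count_nonzero(tissue.phase[live] == Phase.G1) / n)


def cycle_statistics(tissue: Tissue) -> pd.DataFrame:
    """One row per completed cell cycle (birth to division).

    Columns: cell_id, birth_time, division_time, cycle_time,
    area_at_mitosis, generation.
    """
    rows = [
        (cid, birth_t, t, t - birth_t, area, gen)
        for (t, cid, area, birth_t, gen) in tissue.division_records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "birth_time",
            "division_time",
            "cycle_time",
            "area_at_mitosis",
            "generation",
        ],
    )


def record_timeseries_row(tissue: Tissue) -> dict:
    """One sample of the standard time series for the current state."""
    from .decisions import local_densities

    live = tissue.alive & (tissue.phase != Phase.APOPTOTIC) & (tissue.area > 0)
    n_live = int(live.sum())
    row = {
        "t": tissue.t,
        "n_cells": tissue.n_cells,
        "colony_area": tissue.colony_area(),
        "mean_area": float(tissue.area[live].mean()) if n_live else np.nan,
        "mean_density": np.nan,
        "g1_fraction": np.nan,
        "boundary_pressure_gradient": np.nan,
    }
    if n_live:
        rho = local_densities(tissue, normalized=True)
        row["mean_density"] = float(rho[live].mean())
        row["g1_fraction"] = g1_fraction(tissue)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                row["boundary_pressure_gradient"] = boundary_pressure_gradient(tissue)
            except ValueError:
                pass
    return row
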