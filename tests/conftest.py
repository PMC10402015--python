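"""Shared fixtures: desk-scale parameter sets and cached simulation runs.

Simulations run at a reduced scale (sizer threshold AS = 100 sites, timer
tau0 = 40 MCS) that preserves the default configuration's dimensionless
groups, so the suite stays fast while exercising the same physics.
Expensive runs are session-scoped and reused across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from pottsgrowth import run_surviving
from pottsgrowth.params import SimParams, calibrated_params

DESK_AS = 100.0
DESK_TAU0 = 40.0

PHENO_SEEDS = (11, 22, 33)
SWEEP_SEEDS = (7, 17)


def desk_params(box_over_As: float = 100.0, **overrides) -> SimParams:
    """Calibrated default parameters rescaled to desk resolution."""
    p = calibrated_params(DESK_AS, 1.0, DESK_TAU0).replace(
        box_area=box_over_As * DESK_AS, t_max=4000
    )
    return p.replace(**overrides) if overrides else p


@pytest.fixture(scope="session")
def phenomenology_runs():
    """Growth-to-homeostasis runs, apoptosis on and off, three seeds each."""
    base = desk_params()
    runs = {}
    for seed in PHENO_SEEDS:
        for apop in (False, True):
            runs[(seed, apop)] = run_surviving(
                base.replace(seed=seed, apoptosis_enabled=apop),
                record_radial=True,
            )
    return runs


@pytest.fixture(scope="session")
def tgrowth_sweep():
    """Colony-growth runs to confluence across G, lambda and k levels.

    A larger confinement (400 AS) is used so the colony develops a real
    bulk; the elastic modulus is varied alone (the Metropolis temperature
    is an algorithmic constant).  Returns {tag: [summary, ...]} over two
    seeds per level.
    """
    base = desk_params(box_over_As=400.0, t_max=12000, apoptosis_enabled=False)
    grid = {
        "base": base,
        "G_half": base.replace(G=base.G / 2),
        "G_x2": base.replace(G=base.G * 2),
        "lam_half": base.replace(lam=base.lam / 2),
        "lam_x2": base.replace(lam=base.lam * 2),
        "k_quarter": base.replace(k=base.k / 4),
        "k_x4": base.replace(k=base.k * 4),
    }
    out = {}
    for tag, p in grid.items():
        out[tag] = [
            run_surviving(p.replace(seed=s), stop_at=0.995).summary()
            for s in SWEEP_SEEDS
        ]
    return out


@pytest.fixture(scope="session")
def density_sweep():
    """Homeostatic runs (apoptosis on) for the density-control comparison."""
    base = desk_params(seed=7)
    big = calibrated_params(2 * DESK_AS, 1.0, DESK_TAU0).replace(
        box_area=100.0 * 2 * DESK_AS, t_max=4000, seed=7
    )
    grid = {
        "base": base,
        "G_x2": base.replace(G=base.G * 2),
        "lam_x2": base.replace(lam=base.lam * 2),
        "k_x2": base.replace(k=base.k * 2),
        "Jcc_half": base.replace(Jcc=base.Jcc / 2),
        "As_x2": big,
    }
    return {tag: run_surviving(p).summary() for tag, p in grid.items()}


def mean_of(summaries, key):
    return float(np.mean([s[key] for s in summaries]))
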