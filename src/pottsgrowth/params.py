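"""Model parameters, the sizer/timer-based unit system, and rescaling.

The simulator's natural units are lattice sites (area) and Monte Carlo
steps, MCS (time).  The reference default parameter set is expressed in
units built from the G1 sizer threshold ``AS``, the S/G2/M timer ``tau0``
and the area elastic modulus ``lambda``; :func:`resolve_lattice_units`
converts those scale factors into concrete lattice-unit numbers, and
:func:`rescale_params` moves a parameter set to a different (``AS``,
``tau0``) while holding every dimensionless group fixed, which is how
desk-scale simulations that are faithful replicas of the full-scale
conditions are produced.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "SimParams",
    "ContinuumParams",
    "TABLE_SCALINGS",
    "resolve_lattice_units",
    "rescale_params",
    "dimensionless_groups",
    "load_config",
    "save_config",
    "default_params",
]

#: Default-parameter scale factors: each value multiplies the indicated
#: power of the sizer threshold AS (area), the timer tau0 (time) and the
#: elastic modulus lambda (energy/area^2).
TABLE_SCALINGS = {
    "kBT": 1.95e-4,  # x lambda * AS^2
    "Jcc": 1.17e-4,  # x lambda * AS^1.5
    "Jcm": 1.96e-4,  # x lambda * AS^1.5
    "k": 1.897e5,  # x AS^-2
    "G": 1.16,  # x AS / tau0
    "rho_half": 1.5015,  # x AS^-1
    "alpha": 0.968,  # x AS
    "papo_max": 0.0015,  # probability per MCS at tau0 = 225 MCS
    "tau0_rel_sd": 5.625 / 225.0,  # tau0 = 225 +/- 5.625 MCS
    "As_rel_sd": 34.4 / 1377.0,  # AS = 1377 +/- 34.4 sites
    "box_over_As": 1600.0,  # confinement area ~ 1600 AS
}

#: Reference sizer threshold (lattice sites) of the default parameter set.
DEFAULT_AS = 1377.0
#: Reference timer duration (MCS) of the default parameter set.
DEFAULT_TAU0 = 225.0

#: Smallest admissible mean sizer threshold: cells must remain resolvable
#: on the lattice.
MIN_AS = 25.0

#: Calibrated dimensionless groups of the default simulation
#: configuration (see docs/methods.md for the full argument).  The
#: growth law suppresses growth by exp(-k * dA^2), so the contact-
#: inhibition sensor scale 1/sqrt(k) must sit well above the lattice
#: layer's intrinsic area noise (else all growth, including isolated
#: cells, is suppressed and nothing grows) and well below the cell area
#: (else crowding is never sensed).  The reference conversion factors
#: place the noise floor at ~0.1 AS and the sensor at ~0.002 AS — in the
#: wrong order.  The calibrated pair puts the noise floor at ~0.006 AS
#: (temperature group 2e-5) and the sensor at 0.05 AS (crowding group
#: 400), restoring timer-like uncrowded growth together with strong,
#: pressure-regulated contact inhibition.
CALIBRATED_TEMPERATURE_GROUP = 2e-5  # kBT / (lambda * AS^2)
CALIBRATED_CROWDING_GROUP = 400.0  # k * AS^2

# Gaussian draws of per-cell thresholds are truncated at +/- 3 SD and
# floored to keep them physical.
TRUNC_SD = 3.0
AREA_FLOOR = 25.0  # sites
TIME_FLOOR = 1.0  # MCS


@dataclass(frozen=True)
class SimParams:
    """Full parameter set of the lattice simulation, in lattice units.

    Energies are in the same (arbitrary) unit as ``kBT``; areas in lattice
    sites; times in MCS.
    """

    kBT: float
    Jcc: float
    Jcm: float
    lam: float
    G: float
    k: float
    tau0_mean: float
    tau0_sd: float
    As_mean: float
    As_sd: float
    papo_max: float
    rho_half: float
    alpha: float
    box_area: float
    seed: int = 0
    t_max: int = 1000
    apoptosis_enabled: bool = True

    def __post_init__(self) -> None:
        pos = {
            "kBT": self.kBT,
            "Jcc": self.Jcc,
            "Jcm": self.Jcm,
            "lam": self.lam,
            "G": self.G,
            "k": self.k,
            "tau0_mean": self.tau0_mean,
            "As_mean": self.As_mean,
            "papo_max": self.papo_max,
            "rho_half": self.rho_half,
            "alpha": self.alpha,
            "box_area": self.box_area,
        }
        for name, value in pos.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.papo_max > 1:
            raise ValueError("papo_max is a probability and must be <= 1")
        if self.Jcc > self.Jcm:
            raise ValueError(
                "cell-cell adhesion must be at least as strong as cell-medium "
                f"adhesion (Jcc <= Jcm); got Jcc={self.Jcc}, Jcm={self.Jcm}"
            )
        if not self.tau0_sd >= 0 or not self.As_sd >= 0:
            raise ValueError("threshold SDs must be non-negative")
        if self.tau0_sd >= self.tau0_mean:
            raise ValueError("tau0_sd must be smaller than tau0_mean")
        if self.As_sd >= self.As_mean:
            raise ValueError("As_sd must be smaller than As_mean")
        if self.t_max < 0:
            raise ValueError("t_max must be non-negative")

    @property
    def side(self) -> int:
        """Side length of the square confinement lattice, in sites."""
        return int(math.ceil(math.sqrt(self.box_area)))

    def replace(self, **changes: Any) -> "SimParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ContinuumParams:
    """Parameters of the whole-colony continuum model.

    ``G`` is the single-cell growth rate, ``a0`` the area of a newborn
    isolated cell, ``lam`` the stress relaxation rate, ``k`` the crowding
    sensitivity and ``Amax`` the confinement area.  The scaled convention
    a0 = 1, time in 1/lam is obtained simply by passing those values.
    """

    G: float = 1.0
    a0: float = 1.0
    lam: float = 1.0
    k: float = 0.01
    Amax: float = 800.0

    def __post_init__(self) -> None:
        for name in ("G", "a0", "lam", "k", "Amax"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.Amax > self.a0:
            raise ValueError("Amax must exceed the newborn cell area a0")


def resolve_lattice_units(
    As_mean: float = DEFAULT_AS,
    lam: float = 1.0,
    tau0_mean: float = DEFAULT_TAU0,
    *,
    box_area: float | None = None,
    seed: int = 0,
    t_max: int = 1000,
    apoptosis_enabled: bool = True,
) -> SimParams:
    """Resolve the default scaled parameter set to concrete lattice units.

    Given a concrete sizer threshold (sites), elastic modulus and timer
    duration (MCS), every other parameter follows from the reference
    scale factors, e.g. ``kBT = 1.95e-4 * lam * AS**2`` and
    ``G = 1.16 * AS / tau0``.  The apoptosis probability is per MCS and
    scales with the timer so that the expected number of apoptosis
    decisions per cell cycle is invariant.
    """
    if not As_mean > 0 or not lam > 0 or not tau0_mean > 0:
        raise ValueError("As_mean, lam and tau0_mean must be strictly positive")
    s = TABLE_SCALINGS
    return SimParams(
        kBT=s["kBT"] * lam * As_mean**2,
        Jcc=s["Jcc"] * lam * As_mean**1.5,
        Jcm=s["Jcm"] * lam * As_mean**1.5,
        lam=lam,
        G=s["G"] * As_mean / tau0_mean,
        k=s["k"] / As_mean**2,
        tau0_mean=tau0_mean,
        tau0_sd=s["tau0_rel_sd"] * tau0_mean,
        As_mean=As_mean,
        As_sd=s["As_rel_sd"] * As_mean,
        papo_max=s["papo_max"] * DEFAULT_TAU0 / tau0_mean,
        rho_half=s["rho_half"] / As_mean,
        alpha=s["alpha"] * As_mean,
        box_area=box_area if box_area is not None else s["box_over_As"] * As_mean,
        seed=seed,
        t_max=t_max,
        apoptosis_enabled=apoptosis_enabled,
    )


def calibrated_params(
    As_mean: float = DEFAULT_AS,
    lam: float = 1.0,
    tau0_mean: float = DEFAULT_TAU0,
    *,
    temperature_group: float = CALIBRATED_TEMPERATURE_GROUP,
    crowding_group: float = CALIBRATED_CROWDING_GROUP,
    **kwargs: Any,
) -> SimParams:
    """Simulation defaults: reference scalings with a calibrated sensor.

    Identical to :func:`resolve_lattice_units` except for the Metropolis
    temperature and the crowding sensitivity, whose reference conversion
    factors are mutually inconsistent (the contact-inhibition sensor
    scale falls below the thermal area-noise floor, suppressing all
    growth); the calibrated pair restores the intended dynamics.  See
    docs/methods.md.  Note the temperature is an algorithmic constant:
    sweeps over the elastic modulus ``lam`` should vary ``lam`` alone,
    not re-derive kBT.
    """
    p = resolve_lattice_units(As_mean, lam, tau0_mean, **kwargs)
    return p.replace(
        kBT=temperature_group * lam * As_mean**2,
        k=crowding_group / As_mean**2,
    )


def dimensionless_groups(p: SimParams) -> dict[str, float]:
    """The dimensionless combinations that define a simulation condition.

    Two parameter sets with identical groups are replicas of the same
    physical condition at different lattice/temporal resolution.
    """
    As, tau0, lam = p.As_mean, p.tau0_mean, p.lam
    return {
        "kBT/(lam*As^2)": p.kBT / (lam * As**2),
        "Jcc/(lam*As^1.5)": p.Jcc / (lam * As**1.5),
        "Jcm/(lam*As^1.5)": p.Jcm / (lam * As**1.5),
        "k*As^2": p.k * As**2,
        "G*tau0/As": p.G * tau0 / As,
        "rho_half*As": p.rho_half * As,
        "alpha/As": p.alpha / As,
        "papo_max*tau0": p.papo_max * tau0,
        "tau0_sd/tau0": p.tau0_sd / tau0,
        "As_sd/As": p.As_sd / As,
        "box_area/As": p.box_area / As,
    }


def rescale_params(p: SimParams, new_As: float, new_tau0: float) -> SimParams:
    """Rescale a parameter set to a new (AS, tau0) resolution.

    Every dimensionless group of :func:`dimensionless_groups` is preserved
    exactly; only the lattice/temporal resolution changes.  ``t_max`` is
    rescaled in proportion to ``tau0`` (rounded up to a whole MCS).
    """
    if not new_As >= MIN_AS:
        raise ValueError(
            f"new_As={new_As} is too small: cells of fewer than {MIN_AS:.0f} "
            "sites are not resolvable on the lattice"
        )
    if not new_tau0 > 0:
        raise ValueError("new_tau0 must be strictly positive")
    As, tau0, lam = p.As_mean, p.tau0_mean, p.lam
    ra, rt = new_As / As, new_tau0 / tau0
    return p.replace(
        kBT=p.kBT * ra**2,
        Jcc=p.Jcc * ra**1.5,
        Jcm=p.Jcm * ra**1.5,
        G=p.G * ra / rt,
        k=p.k / ra**2,
        tau0_mean=new_tau0,
        tau0_sd=p.tau0_sd * rt,
        As_mean=new_As,
        As_sd=p.As_sd * ra,
        papo_max=p.papo_max / rt,
        rho_half=p.rho_half / ra,
        alpha=p.alpha * ra,
        box_area=p.box_area * ra,
        t_max=int(math.ceil(p.t_max * rt)),
    )


def default_params(**overrides: Any) -> SimParams:
    """The packaged default configuration, resolved to lattice units."""
    with resources.files("pottsgrowth.data").joinpath("default_params.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    cfg.update(overrides)
    return SimParams(**cfg)


def load_config(path: str | Path) -> SimParams:
    """Load a YAML/JSON configuration whose keys match SimParams fields."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration file {path} does not hold a mapping")
    known = {f.name for f in dataclasses.fields(SimParams)}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(
            f"unknown configuration keys {sorted(unknown)}; valid keys: {sorted(known)}"
        )
    return SimParams(**cfg)


def save_config(p: SimParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(p.to_dict(), fh, sort_keys=False)
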