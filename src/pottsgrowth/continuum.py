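"""Whole-colony continuum model.

The colony is a single elastic medium of area ``A`` relaxing toward a
preferred area ``A0`` at rate ``lam``, while ``A0`` grows logistically
toward the confinement area ``Amax`` at a crowding-suppressed rate:

    dA/dt  = -lam * (A - A0)
    dA0/dt = (G / a0) * exp(-k * (A - A0)^2) * A0 * (1 - A0 / Amax)

The attracting fixed point is A = A0 = Amax.  Integration is classical
fixed-step fourth-order Runge-Kutta; halving the step changes the result
well below the 1e-6 relative convergence contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ContinuumParams

__all__ = [
    "ContinuumTrajectory",
    "continuum_rhs",
    "integrate_continuum",
    "integrate_to_steady_state",
    "continuum_tgrowth",
    "continuum_max_pressure",
]


@dataclass
class ContinuumTrajectory:
    """Sampled (t, A, A0) series with the parameters that produced it."""

    t: np.ndarray
    A: np.ndarray
    A0: np.ndarray
    params: ContinuumParams

    def pressure(self) -> np.ndarray:
        """Tissue pressure lam * (A0 - A): positive when compressed."""
        return self.params.lam * (self.A0 - self.A)


def continuum_rhs(A: float, A0: float, p: ContinuumParams) -> tuple[float, float]:
    """(dA/dt, dA0/dt) of the continuum model."""
    if A <= 0 or A0 <= 0:
        raise ValueError("areas must be strictly positive")
    dA = -p.lam * (A - A0)
    dA0 = (p.G / p.a0) * np.exp(-p.k * (A - A0) ** 2) * A0 * (1.0 - A0 / p.Amax)
    return dA, dA0


def _rk4_step(A, A0, dt, p):
    try:
        return _rk4_substeps(A, A0, dt, p)
    except ValueError as err:  # rhs evaluated at nonpositive areas
        raise RuntimeError(
            f"integration left the invariant region ({err}); reduce dt"
        ) from err


def _rk4_substeps(A, A0, dt, p):
    k1 = continuum_rhs(A, A0, p)
    k2 = continuum_rhs(A + 0.5 * dt * k1[0], A0 + 0.5 * dt * k1[1], p)
    k3 = continuum_rhs(A + 0.5 * dt * k2[0], A0 + 0.5 * dt * k2[1], p)
    k4 = continuum_rhs(A + dt * k3[0], A0 + dt * k3[1], p)
    A_new = A + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    A0_new = A0 + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    return A_new, A0_new


def integrate_continuum(
    p: ContinuumParams,
    t_end: float,
    dt: float | None = None,
    record_every: int | None = None,
) -> ContinuumTrajectory:
    """Integrate from A(0) = A0(0) = a0 up to ``t_end`` with RK4.

    ``dt`` defaults to 1e-3 / lam.  ``record_every`` thins the stored
    samples (the final state is always recorded exactly at the last
    step).  Raises if the solution leaves its invariant region
    (0 < A, A0 <= Amax), which signals an unstable step size.
    """
    if dt is None:
        dt = 1e-3 / p.lam
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(np.ceil(t_end / dt))
    if record_every is None:
        record_every = max(1, n_steps // 20000)
    A, A0 = p.a0, p.a0
    ts, As, A0s = [0.0], [A], [A0]
    cap = p.Amax * (1.0 + 1e-9)
    for i in range(1, n_steps + 1):
        A, A0 = _rk4_step(A, A0, dt, p)
        if not (0 < A) or not (0 < A0 <= cap):
            raise RuntimeError(
                f"integration left the invariant region at t={i * dt:.6g} "
                f"(A={A!r}, A0={A0!r}); reduce dt"
            )
        if i % record_every == 0 or i == n_steps:
            ts.append(i * dt)
            As.append(A)
            A0s.append(A0)
    return ContinuumTrajectory(
        np.asarray(ts), np.asarray(As), np.asarray(A0s), p
    )


def integrate_to_steady_state(
    p: ContinuumParams,
    dt: float | None = None,
    deriv_tol: float = 1e-10,
    t_max: float = 1e5,
) -> ContinuumTrajectory:
    """Integrate from (a0, a0) until both derivatives fall below tolerance."""
    if dt is None:
        dt = 1e-3 / p.lam
    A, A0 = p.a0, p.a0
    ts, As, A0s = [0.0], [A], [A0]
    t = 0.0
    check_every = max(1, int(round(0.1 / (dt * p.lam))))
    i = 0
    while t < t_max:
        A, A0 = _rk4_step(A, A0, dt, p)
        t += dt
        i += 1
        if i % check_every == 0:
            ts.append(t)
            As.append(A)
            A0s.append(A0)
            dA, dA0 = continuum_rhs(A, A0, p)
            if abs(dA) < deriv_tol and abs(dA0) < deriv_tol:
                return ContinuumTrajectory(
                    np.asarray(ts), np.asarray(As), np.asarray(A0s), p
                )
    raise RuntimeError(f"no steady state reached by t={t_max}")


def continuum_tgrowth(
    traj: ContinuumTrajectory, Amax: float | None = None, frac: float = 0.95
):
    """Time for the colony area to reach ``frac * Amax`` (interpolated).

    Returns None if the trajectory never crosses the threshold.
    """
    Amax = traj.params.Amax if Amax is None else Amax
    threshold = frac * Amax
    above = traj.A >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(traj.t[0])
    t0, t1 = traj.t[i - 1], traj.t[i]
    a0, a1 = traj.A[i - 1], traj.A[i]
    if a1 == a0:
        return float(t1)
    return float(t0 + (threshold - a0) * (t1 - t0) / (a1 - a0))


def continuum_max_pressure(traj: ContinuumTrajectory, lam: float | None = None) -> float:
    """Maximum over time of the tissue pressure lam * (A0 - A)."""
    lam = traj.params.lam if lam is None else lam
    return float(np.max(lam * (traj.A0 - traj.A)))
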