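"""Lagrangian particle tracking and along-trajectory kinetics.

The Lagrangian view of the same physics: a microalgal cell is a massless
tracer of the steady flow, its "irradiance history" u(t) is the light field
sampled along its trajectory, and its photosynthetic state evolves by the
PSF ODE driven by that history.  A closed orbit spanning the culture depth
turns the steady light gradient into hydrodynamically induced light/dark
cycles -- the mechanism behind the flashing-light enhancement.  Used as an
independent cross-check of the Eulerian transport solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


from .flow import VelocityField2D
from .kinetics import (KineticsTrajectory, PSFReparam, PSFState,
                       CASE_STUDY_REPARAM, simulate_full)
from .light import LightField

__all__ = ["Trajectory", "IrradianceHistory", "trace", "irradiance_history",
           "kinetics_along"]


@dataclass
class Trajectory:
    """Particle path: times t (s) and positions x, z (m), strictly in-domain."""

    t: np.ndarray
    x: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("trajectory times must be strictly increasing")


@dataclass
class IrradianceHistory:
    """Normalized irradiance u(t) sampled on a trajectory's time grid."""

    t: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.u < 0):
            raise ValueError("irradiance history must be non-negative")

    def interpolant(self):
        """Piecewise-linear u(t), clamped to the end values outside the range."""
        t, u = self.t, self.u
        return lambda tt: float(np.interp(tt, t, u))

    def time_average(self) -> float:
        return float(np.trapezoid(self.u, self.t) / (self.t[-1] - self.t[0]))


class _Interp:
    """Bilinear velocity interpolation on cell centers, clamped at walls.

    Hand-rolled index arithmetic on the uniform grid; an order of magnitude
    faster per evaluation than a general scattered-point interpolator, which
    matters because RK4 calls it four times per step.
    """

    def __init__(self, field: VelocityField2D):
        g = field.grid
        self._x0, self._dx, self._nx = g.x_centers[0], g.dx, g.nx
        self._z0, self._dz, self._nz = g.z_centers[0], g.dz, g.nz
        self._vx, self._vz = field.vx, field.vz

    def __call__(self, x: float, z: float) -> tuple[float, float]:
        fx = min(max((x - self._x0) / self._dx, 0.0), self._nx - 1.000001)
        fz = min(max((z - self._z0) / self._dz, 0.0), self._nz - 1.000001)
        i, j = int(fx), int(fz)
        tx, tz = fx - i, fz - j
        w00 = (1 - tx) * (1 - tz)
        w01 = tx * (1 - tz)
        w10 = (1 - tx) * tz
        w11 = tx * tz
        vx = (w00 * self._vx[j, i] + w01 * self._vx[j, i + 1]
              + w10 * self._vx[j + 1, i] + w11 * self._vx[j + 1, i + 1])
        vz = (w00 * self._vz[j, i] + w01 * self._vz[j, i + 1]
              + w10 * self._vz[j + 1, i] + w11 * self._vz[j + 1, i + 1])
        return vx, vz


def trace(velocity: VelocityField2D, x0: tuple[float, float], T: float,
          dt: float) -> Trajectory:
    """Integrate dx/dt = v(x) with classical RK4 from position ``x0``.

    The velocity is bilinearly interpolated between cell centers (clamped to
    the nearest center beyond them).  Walls are impermeable: a sub-step that
    would leave the cavity is specularly reflected back inside.  Starting
    exactly on a stagnation point (e.g. a corner) yields a stationary
    trajectory with a warning.
    """
    g = velocity.grid
    x, z = float(x0[0]), float(x0[1])
    if not (0.0 <= x <= g.L and 0.0 <= z <= g.L):
        raise ValueError(f"start position {x0!r} outside the [0, {g.L}]^2 domain")
    interp = _Interp(velocity)
    v0 = interp(x, z)
    vmax = velocity.max_speed
    if vmax > 0.0 and np.hypot(*v0) < 1e-10 * vmax:
        warnings.warn(f"start position {x0!r} is a stagnation point; "
                      "trajectory is stationary", stacklevel=2)
    n = int(round(T / dt))
    ts = np.arange(n + 1) * dt
    xs = np.empty(n + 1)
    zs = np.empty(n + 1)
    xs[0], zs[0] = x, z
    for k in range(n):
        k1 = interp(x, z)
        k2 = interp(x + 0.5 * dt * k1[0], z + 0.5 * dt * k1[1])
        k3 = interp(x + 0.5 * dt * k2[0], z + 0.5 * dt * k2[1])
        k4 = interp(x + dt * k3[0], z + dt * k3[1])
        x += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        z += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        # specular reflection at impermeable walls
        if x < 0.0:
            x = -x
        elif x > g.L:
            x = 2 * g.L - x
        if z < 0.0:
            z = -z
        elif z > g.L:
            z = 2 * g.L - z
        xs[k + 1], zs[k + 1] = x, z
    return Trajectory(t=ts, x=xs, z=zs)


def irradiance_history(traj: Trajectory, light: LightField) -> IrradianceHistory:
    """Concatenate a trajectory with the light field: u(t) = u(z(t)).

    On a periodic orbit spanning the depth this is the hydrodynamically
    induced light/dark cycle, oscillating between ~u0 near the illuminated
    wall and ~u0*exp(-Ot) at the far side.
    """
    z = np.clip(traj.z, 0.0, light.L)
    return IrradianceHistory(t=traj.t.copy(), u=light.irradiance_at(z))


def kinetics_along(history: IrradianceHistory,
                   reparam: PSFReparam = CASE_STUDY_REPARAM,
                   y0: PSFState = PSFState(1.0, 0.0, 0.0),
                   dt_out: float | None = None) -> KineticsTrajectory:
    """Integrate the full PSF model driven by an irradiance history.

    The history is interpolated piecewise-linearly in time and fed to the
    stiff integrator; for a constant history this reduces to constant-light
    `simulate_full`.
    """
    u_of_t = history.interpolant()
    return simulate_full(u_of_t, y0, (float(history.t[0]), float(history.t[-1])),
                         dt_out=dt_out, reparam=reparam)
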