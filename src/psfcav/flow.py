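"""Steady incompressible 2-D lid-driven-cavity flow and analytic fixtures.

The square cavity with a tangentially moving top wall stands in for one
Taylor-vortex cell of a photobioreactor: the lid drives a primary
recirculation that carries cells between the bright bottom and the dark top
of the culture.  The solver uses the streamfunction-vorticity formulation
(2-D, steady, no pressure unknown): explicit pseudo-time stepping of the
vorticity transport equation with a direct prefactorized sparse solve of the
Poisson equation for the streamfunction at every step, and Thom's
first-order wall-vorticity closure.  It is a laminar solver; above
Re ~ 5000 a warning is issued and the well-mixed regime should instead be
emulated by the transport module's ideal-mixing mode.

Velocities are cell-centered; the node streamfunction is kept alongside so
that the transport solver can build exactly divergence-free face fluxes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = [
    "Grid2D", "VelocityField2D", "CavityConvergenceError", "solve_cavity",
    "analytic_vortex", "reynolds", "write_field", "read_field",
]

#: Kinematic viscosity of water at ~20 C (m^2 s^-1); with L = 0.02 m this is
#: the value under which the transport/reaction time-scale ratio obeys
#: Da = 260/Re for the case-study kinetics.
NU_WATER = 1.0e-6


class CavityConvergenceError(RuntimeError):
    """Raised when the pseudo-time iteration fails to reach tolerance."""


@dataclass(frozen=True)
class Grid2D:
    """Uniform cell-centered grid on the square [0, L] x [0, L].

    ``nx`` columns (x-direction) by ``nz`` rows (z-direction, height above
    the illuminated bottom wall).  Nodes (cell corners) are at
    ``i*dx, j*dz``; centers at offsets of half a spacing.
    """

    nx: int
    nz: int
    L: float

    def __post_init__(self) -> None:
        if self.nx < 4 or self.nz < 4:
            raise ValueError(f"grid must be at least 4x4, got {self.nx}x{self.nz}")
        if not self.L > 0.0:
            raise ValueError(f"side length L must be positive, got {self.L!r}")

    @property
    def dx(self) -> float:
        return self.L / self.nx

    @property
    def dz(self) -> float:
        return self.L / self.nz

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.dz

    @property
    def x_nodes(self) -> np.ndarray:
        return np.arange(self.nx + 1) * self.dx

    @property
    def z_nodes(self) -> np.ndarray:
        return np.arange(self.nz + 1) * self.dz


@dataclass
class VelocityField2D:
    """Steady velocity on a `Grid2D`: cell-centered (vx, vz) in m s^-1.

    ``psi`` (node streamfunction, shape (nz+1, nx+1), m^2 s^-1) is optional;
    when present the transport solver derives face fluxes from psi
    differences, which makes the discrete field exactly divergence-free.
    """

    grid: Grid2D
    vx: np.ndarray
    vz: np.ndarray
    lid_velocity: float = 0.0
    nu: float = NU_WATER
    psi: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        shape = (self.grid.nz, self.grid.nx)
        if self.vx.shape != shape or self.vz.shape != shape:
            raise ValueError(f"velocity arrays must have shape {shape}, got "
                             f"{self.vx.shape} and {self.vz.shape}")
        if self.psi is not None and self.psi.shape != (self.grid.nz + 1,
                                                       self.grid.nx + 1):
            raise ValueError("psi must live on grid nodes "
                             f"(shape {(self.grid.nz + 1, self.grid.nx + 1)})")

    @property
    def reynolds(self) -> float:
        """Re = v_L * L / nu based on the lid velocity."""
        return reynolds(self.lid_velocity, self.grid.L, self.nu)

    @property
    def max_speed(self) -> float:
        return float(np.sqrt(self.vx ** 2 + self.vz ** 2).max())

    def kinetic_energy(self) -> float:
        """Cell-mean kinetic energy per unit mass, 0.5 <|v|^2> (m^2 s^-2)."""
        return float(0.5 * np.mean(self.vx ** 2 + self.vz ** 2))

    def divergence(self) -> np.ndarray:
        """Central-difference divergence on interior cells, shape (nz-2, nx-2)."""
        g = self.grid
        ddx = (self.vx[1:-1, 2:] - self.vx[1:-1, :-2]) / (2.0 * g.dx)
        ddz = (self.vz[2:, 1:-1] - self.vz[:-2, 1:-1]) / (2.0 * g.dz)
        return ddx + ddz

    def face_velocities(self) -> tuple[np.ndarray, np.ndarray]:
        """Normal velocities on cell faces: (u_face (nz, nx+1), w_face (nz+1, nx)).

        From psi differences when available (telescoping makes every cell's
        flux balance exactly zero and wall-normal fluxes vanish); otherwise
        by averaging adjacent cell-centered values with zero walls.
        """
        g = self.grid
        if self.psi is not None:
            u_face = (self.psi[1:, :] - self.psi[:-1, :]) / g.dz
            w_face = -(self.psi[:, 1:] - self.psi[:, :-1]) / g.dx
            return u_face, w_face
        u_face = np.zeros((g.nz, g.nx + 1))
        u_face[:, 1:-1] = 0.5 * (self.vx[:, 1:] + self.vx[:, :-1])
        w_face = np.zeros((g.nz + 1, g.nx))
        w_face[1:-1, :] = 0.5 * (self.vz[1:, :] + self.vz[:-1, :])
        return u_face, w_face


def reynolds(v_L: float, L: float, nu: float) -> float:
    """Reynolds number Re = v_L * L / nu of the lid-driven cavity."""
    if not (L > 0.0 and nu > 0.0):
        raise ValueError(f"L and nu must be positive, got L={L!r}, nu={nu!r}")
    return v_L * L / nu


def analytic_vortex(grid: Grid2D, amplitude: float,
                    nu: float = NU_WATER) -> VelocityField2D:
    """Single-cell recirculation from psi = A sin(pi x/L) sin(pi z/L).

    ``amplitude`` is the peak streamfunction A (m^2 s^-1); the peak speed is
    A*pi/L.  The field is exactly divergence-free (it derives from a
    streamfunction) and has zero normal velocity on all four walls.  Serves
    as a closed-streamline fixture replacing a cavity solve in tests.
    """
    if amplitude < 0.0:
        raise ValueError(f"amplitude must be non-negative, got {amplitude!r}")
    L = grid.L
    k = np.pi / L
    x = grid.x_centers[None, :]
    z = grid.z_centers[:, None]
    vx = amplitude * k * np.sin(k * x) * np.cos(k * z)   # d(psi)/dz
    vz = -amplitude * k * np.cos(k * x) * np.sin(k * z)  # -d(psi)/dx
    psi = amplitude * np.outer(np.sin(k * grid.z_nodes), np.sin(k * grid.x_nodes))
    psi[[0, -1], :] = 0.0  # walls are the psi = 0 streamline exactly
    psi[:, [0, -1]] = 0.0
    return VelocityField2D(grid=grid, vx=vx * np.ones_like(vz), vz=vz * np.ones_like(vx),
                           lid_velocity=0.0, nu=nu, psi=psi)


def _interior_laplacian(n: int, h: float):
    """Prefactorized 5-point Laplacian on the (n-1)^2 interior nodes."""
    m = n - 1
    T = sp.diags([1.0, -2.0, 1.0], [-1, 0, 1], shape=(m, m))
    I = sp.identity(m)
    return splu(((sp.kron(I, T) + sp.kron(T, I)) / h ** 2).tocsc()), m


def solve_cavity(Re: float, grid: Grid2D, tol: float = 1e-7,
                 max_iter: int = 200_000, nu: float = NU_WATER,
                 scheme: str = "auto") -> VelocityField2D:
    """Steady lid-driven-cavity solve at Reynolds number Re.

    Nondimensional solve (unit square, unit lid speed, viscosity 1/Re)
    rescaled afterward to the physical lid velocity v_L = Re*nu/L.
    ``tol`` bounds the relative pseudo-time vorticity residual
    max|d omega/dt| * dt / max|omega|.  ``scheme`` selects central (second
    order) or upwind (first order, bounded at any cell Peclet number)
    convection differencing; "auto" uses central while the cell Peclet
    number Re/n stays below 16 and upwind beyond, where the explicit
    central iteration can diverge.

    Re = 0 means a stationary lid and returns the exactly zero field.
    """
    if Re < 0.0:
        raise ValueError(f"Re must be non-negative, got {Re!r}")
    if grid.nx != grid.nz:
        raise ValueError("cavity solver requires a square grid (nx == nz)")
    if scheme == "auto":
        scheme = "central" if Re / grid.nx <= 16.0 else "upwind"
    if scheme not in ("central", "upwind"):
        raise ValueError(f"unknown scheme {scheme!r}")
    n = grid.nx
    N = n + 1
    zeros = np.zeros((grid.nz, grid.nx))
    if Re == 0.0:
        return VelocityField2D(grid=grid, vx=zeros.copy(), vz=zeros.copy(),
                               lid_velocity=0.0, nu=nu,
                               psi=np.zeros((N, N)))
    if Re > 5000.0:
        warnings.warn(f"Re = {Re:g} is beyond the laminar regime this solver "
                      "resolves; consider the transport module's ideal-mixing "
                      "mode instead", stacklevel=2)

    h = 1.0 / n
    visc = 1.0 / Re
    lu, m = _interior_laplacian(n, h)
    psi = np.zeros((N, N))
    om = np.zeros((N, N))
    u = np.zeros((N, N))
    w = np.zeros((N, N))
    u[-1, :] = 1.0  # lid moves in +x
    dt = 0.8 * min(0.25 * h * h / visc, h)
    res = np.inf
    for it in range(max_iter):
        psi[1:-1, 1:-1] = lu.solve(-om[1:-1, 1:-1].ravel()).reshape(m, m)
        u[1:-1, 1:-1] = (psi[2:, 1:-1] - psi[:-2, 1:-1]) / (2 * h)
        w[1:-1, 1:-1] = -(psi[1:-1, 2:] - psi[1:-1, :-2]) / (2 * h)
        om_new = np.empty_like(om)
        # Thom's wall vorticity (psi = 0 on all walls)
        om_new[0, :] = -2.0 * psi[1, :] / h ** 2
        om_new[-1, :] = -2.0 * (psi[-2, :] + h) / h ** 2
        om_new[:, 0] = -2.0 * psi[:, 1] / h ** 2
        om_new[:, -1] = -2.0 * psi[:, -2] / h ** 2
        oc = om[1:-1, 1:-1]
        uc, wc = u[1:-1, 1:-1], w[1:-1, 1:-1]
        if scheme == "central":
            conv = (uc * (om[1:-1, 2:] - om[1:-1, :-2]) / (2 * h)
                    + wc * (om[2:, 1:-1] - om[:-2, 1:-1]) / (2 * h))
        else:
            dodx = np.where(uc > 0, (oc - om[1:-1, :-2]) / h,
                            (om[1:-1, 2:] - oc) / h)
            dodz = np.where(wc > 0, (oc - om[:-2, 1:-1]) / h,
                            (om[2:, 1:-1] - oc) / h)
            conv = uc * dodx + wc * dodz
        lap = (om[1:-1, 2:] + om[1:-1, :-2] + om[2:, 1:-1] + om[:-2, 1:-1]
               - 4 * oc) / h ** 2
        om_new[1:-1, 1:-1] = oc + dt * (-conv + visc * lap)
        res = float(np.max(np.abs(om_new - om)) / max(np.max(np.abs(om)), 1.0))
        om = om_new
        if not np.isfinite(res):
            raise CavityConvergenceError(
                f"cavity solve at Re = {Re:g} diverged after {it} iterations "
                f"({scheme} convection on a {n}x{n} grid); refine the grid or "
                "use scheme='upwind'")
        if res < tol:
            break
    else:
        raise CavityConvergenceError(
            f"cavity solve at Re = {Re:g} did not converge within {max_iter} "
            f"iterations (final relative residual {res:.3e} > tol {tol:.3e})")
    psi[1:-1, 1:-1] = lu.solve(-om[1:-1, 1:-1].ravel()).reshape(m, m)

    v_L = Re * nu / grid.L
    scale = v_L  # nondimensional velocities are in lid units
    # cell-centered velocities from the node streamfunction (consistent with
    # the face fluxes the transport solver derives from psi)
    psi_phys = psi * v_L * grid.L
    u_face = (psi_phys[1:, :] - psi_phys[:-1, :]) / grid.dz
    w_face = -(psi_phys[:, 1:] - psi_phys[:, :-1]) / grid.dx
    vx = 0.5 * (u_face[:, 1:] + u_face[:, :-1])
    vz = 0.5 * (w_face[1:, :] + w_face[:-1, :])
    return VelocityField2D(grid=grid, vx=vx, vz=vz, lid_velocity=scale,
                           nu=nu, psi=psi_phys)


def write_field(field: VelocityField2D, path: str | Path) -> None:
    """Write a velocity field as CSV (x, z, vx, vz) with grid metadata.

    The node streamfunction, when present, is stored in a sidecar file
    ``<path>.psi`` so that the roundtrip preserves the divergence-free face
    fluxes.
    """
    path = Path(path)
    g = field.grid
    X, Z = np.meshgrid(g.x_centers, g.z_centers)
    df = pd.DataFrame({"x": X.ravel(), "z": Z.ravel(),
                       "vx": field.vx.ravel(), "vz": field.vz.ravel()})
    with open(path, "w") as fh:
        fh.write(f"# psfcav-velocity-field nx={g.nx} nz={g.nz} L={g.L!r} "
                 f"lid_velocity={field.lid_velocity!r} nu={field.nu!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    if field.psi is not None:
        np.savetxt(str(path) + ".psi", field.psi, fmt="%.17g")


def read_field(path: str | Path) -> VelocityField2D:
    """Read a velocity field written by `write_field` (lossless roundtrip)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("# psfcav-velocity-field"):
        raise ValueError(f"{path}: not a psfcav velocity-field CSV "
                         "(missing header line)")
    meta = dict(tok.split("=", 1) for tok in header.split()[2:])
    try:
        g = Grid2D(nx=int(meta["nx"]), nz=int(meta["nz"]), L=float(meta["L"]))
        lid = float(meta["lid_velocity"])
        nu = float(meta["nu"])
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{path}: malformed metadata header: {exc}") from exc
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if len(df) != g.nx * g.nz:
        raise ValueError(f"{path}: expected {g.nx * g.nz} rows for a "
                         f"{g.nx}x{g.nz} grid, found {len(df)}")
    vx = df["vx"].to_numpy().reshape(g.nz, g.nx)
    vz = df["vz"].to_numpy().reshape(g.nz, g.nx)
    psi = None
    psi_path = Path(str(path) + ".psi")
    if psi_path.exists():
        psi = np.loadtxt(psi_path)
        if psi.shape != (g.nz + 1, g.nx + 1):
            raise ValueError(f"{psi_path}: streamfunction shape {psi.shape} "
                             f"does not match grid nodes {(g.nz + 1, g.nx + 1)}")
    return VelocityField2D(grid=g, vx=vx, vz=vz, lid_velocity=lid, nu=nu, psi=psi)
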