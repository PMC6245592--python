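"""Legacy-ASCII VTK output for structured 2-D fields.

Writes STRUCTURED_POINTS datasets with cell-centered scalars/vectors placed
as point data at the cell-center coordinates, readable by ParaView/VisIt.
Output only; the package's lossless interchange format is CSV (see
`psfcav.flow.write_field`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .flow import Grid2D

__all__ = ["write_vtk"]


def write_vtk(path: str | Path, grid: Grid2D,
              scalars: dict[str, np.ndarray] | None = None,
              vectors: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
              title: str = "psfcav field") -> None:
    """Write cell-centered fields on ``grid`` as a legacy VTK file.

    ``scalars`` maps names to (nz, nx) arrays; ``vectors`` maps names to
    (vx, vz) pairs of (nz, nx) arrays (the third component is written as 0).
    """
    scalars = scalars or {}
    vectors = vectors or {}
    shape = (grid.nz, grid.nx)
    for name, arr in scalars.items():
        if arr.shape != shape:
            raise ValueError(f"scalar {name!r} has shape {arr.shape}, expected {shape}")
    for name, (ax, az) in vectors.items():
        if ax.shape != shape or az.shape != shape:
            raise ValueError(f"vector {name!r} components must have shape {shape}")

    npts = grid.nx * grid.nz
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {grid.nx} {grid.nz} 1",
        f"ORIGIN {0.5 * grid.dx:.9g} {0.5 * grid.dz:.9g} 0",
        f"SPACING {grid.dx:.9g} {grid.dz:.9g} 1",
        f"POINT_DATA {npts}",
    ]
    for name, arr in scalars.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.9g}" for v in arr.ravel())
    for name, (ax, az) in vectors.items():
        lines.append(f"VECTORS {name} double")
        lines.extend(f"{x:.9g} {z:.9g} 0"
                     for x, z in zip(ax.ravel(), az.ravel()))
    Path(path).write_text("\n".join(lines) + "\n")
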