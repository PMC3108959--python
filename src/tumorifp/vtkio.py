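"""Legacy-VTK ASCII writer for voxel fields (STRUCTURED_POINTS).

Minimal, dependency-free writer for the one layout this package produces:
scalar and vector fields sampled at voxel centers, emitted as POINT_DATA on
a lattice whose origin is the first voxel center.  Readable by ParaView/VisIt.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_structured_points"]


def _fmt(x: float) -> str:
    return f"{x:.9e}"


def write_structured_points(
    path,
    shape: tuple[int, int, int],
    spacing: float,
    origin: tuple[float, float, float],
    scalars: dict[str, np.ndarray] | None = None,
    vectors: dict[str, np.ndarray] | None = None,
    title: str = "tumorifp field",
) -> None:
    """Write scalar fields (shape nx,ny,nz) and vector fields (…,3) to `path`.

    VTK orders points with x varying fastest, so arrays indexed [ix, iy, iz]
    are flattened in Fortran order.
    """
    nx, ny, nz = shape
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(title + "\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {_fmt(origin[0])} {_fmt(origin[1])} {_fmt(origin[2])}\n")
        fh.write(f"SPACING {_fmt(spacing)} {_fmt(spacing)} {_fmt(spacing)}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in (scalars or {}).items():
            arr = np.asarray(arr)
            if arr.shape != (nx, ny, nz):
                raise ValueError(f"scalar {name!r} has shape {arr.shape}, want {shape}")
            fh.write(f"SCALARS {name} double 1\n")
            fh.write("LOOKUP_TABLE default\n")
            for v in arr.ravel(order="F"):
                fh.write(_fmt(v) + "\n")
        for name, arr in (vectors or {}).items():
            arr = np.asarray(arr)
            if arr.shape != (nx, ny, nz, 3):
                raise ValueError(
                    f"vector {name!r} has shape {arr.shape}, want {(nx, ny, nz, 3)}"
                )
            fh.write(f"VECTORS {name} double\n")
            # x varies fastest in VTK point order
            flat = arr.transpose(2, 1, 0, 3).reshape(-1, 3)
            for vx, vy, vz in flat:
                fh.write(f"{_fmt(vx)} {_fmt(vy)} {_fmt(vz)}\n")
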