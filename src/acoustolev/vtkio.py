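"""Minimal legacy-ASCII VTK rectilinear-grid writer for field export.

Writes DATASET RECTILINEAR_GRID files with named scalar point arrays
(Fortran point ordering: x fastest), readable by ParaView/VisIt.
Text-only on purpose.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_rectilinear_vtk"]


def write_rectilinear_vtk(path, x, y, z, point_data: dict) -> None:
    """Write scalar fields of shape (nx, ny, nz) on a rectilinear grid."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    nx, ny, nz = len(x), len(y), len(z)
    lines = [
        "# vtk DataFile Version 3.0",
        "acoustolev field export",
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {nx} {ny} {nz}",
    ]
    for name, arr in (("X", x), ("Y", y), ("Z", z)):
        lines.append(f"{name}_COORDINATES {len(arr)} double")
        lines.append(" ".join(f"{v:.9e}" for v in arr))
    lines.append(f"POINT_DATA {nx * ny * nz}")
    for name, arr in point_data.items():
        arr = np.asarray(arr)
        if arr.shape != (nx, ny, nz):
            raise ValueError(f"field {name!r} shape {arr.shape} != grid")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        flat = arr.transpose(2, 1, 0).ravel()  # z-major -> x fastest
        lines.extend(
            " ".join(f"{v:.9e}" for v in flat[i:i + 6])
            for i in range(0, len(flat), 6)
        )
    Path(path).write_text("\n".join(lines) + "\n")
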