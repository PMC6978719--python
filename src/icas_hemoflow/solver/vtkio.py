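"""Minimal legacy-ASCII VTK structured-grid writer.

Writes the (z, y) meridian/channel plane as a VTK STRUCTURED_GRID with
point-attached scalar and vector fields — enough for ParaView-style
inspection of the solved fields without any binary dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_structured_grid(path, x: np.ndarray, y: np.ndarray,
                          point_data: dict[str, np.ndarray] | None = None,
                          vector_data: dict[str, tuple] | None = None) -> None:
    """Write a 2-D structured grid (ni x nj nodes) in legacy ASCII VTK.

    ``x``/``y`` are (ni, nj) node coordinates; scalars are (ni, nj) arrays;
    vectors are (vx, vy) pairs of (ni, nj) arrays (z-component written as 0).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ni, nj = x.shape
    lines = [
        "# vtk DataFile Version 3.0",
        "icas-hemoflow structured grid",
        "ASCII",
        "DATASET STRUCTURED_GRID",
        # VTK dimensions are (fastest, middle, slowest); we write j fastest.
        f"DIMENSIONS {nj} {ni} 1",
        f"POINTS {ni * nj} double",
    ]
    for i in range(ni):
        for j in range(nj):
            lines.append(f"{x[i, j]:.9e} {y[i, j]:.9e} 0.0")

    point_data = point_data or {}
    vector_data = vector_data or {}
    if point_data or vector_data:
        lines.append(f"POINT_DATA {ni * nj}")
    for name, arr in point_data.items():
        arr = np.asarray(arr, float)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{arr[i, j]:.9e}" for i in range(ni) for j in range(nj))
    for name, (vx, vy) in vector_data.items():
        lines.append(f"VECTORS {name} double")
        lines.extend(f"{vx[i, j]:.9e} {vy[i, j]:.9e} 0.0"
                     for i in range(ni) for j in range(nj))
    Path(path).write_text("\n".join(lines) + "\n")
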