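"""Minimal legacy-ASCII VTK writers for the structured voxel fields.

Writes STRUCTURED_POINTS datasets (cell scalars such as material labels,
stimulus classes or moduli; point vectors such as displacements) readable
by ParaView.  Kept deliberately small: the package only needs structured
grids with uniform spacing.
"""

from __future__ import annotations

import numpy as np


def write_structured_points(
    path,
    n: int,
    spacing: float,
    cell_scalars: dict[str, np.ndarray] | None = None,
    point_vectors: dict[str, np.ndarray] | None = None,
) -> None:
    """Write cell scalars (length n^3, flat C order over (ix,iy,iz)) and/or
    point vectors (length 3*(n+1)^3, dof-interleaved) on the voxel grid.

    Arrays follow the package convention (x slowest); VTK expects x
    fastest, so axes are transposed on output.
    """
    nn = n + 1
    lines = [
        "# vtk DataFile Version 3.0",
        "scaffoldregen field export",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nn} {nn} {nn}",
        "ORIGIN 0 0 0",
        f"SPACING {spacing} {spacing} {spacing}",
    ]
    if point_vectors:
        lines.append(f"POINT_DATA {nn**3}")
        for name, vec in point_vectors.items():
            arr = np.asarray(vec, dtype=float).reshape(nn, nn, nn, 3)
            arr = arr.transpose(2, 1, 0, 3).reshape(-1, 3)  # z-slowest -> x-fastest
            lines.append(f"VECTORS {name} float")
            lines.extend(f"{a:.6g} {b:.6g} {c:.6g}" for a, b, c in arr)
    if cell_scalars:
        lines.append(f"CELL_DATA {n**3}")
        for name, field in cell_scalars.items():
            arr = np.asarray(field).reshape(n, n, n).transpose(2, 1, 0).reshape(-1)
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.6g}" for v in arr)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_lattice(path, lattice) -> None:
    """Export the agent lattice (phenotype and deposited tissue) as cell
    data on the site grid."""
    m = lattice.m
    lines = [
        "# vtk DataFile Version 3.0",
        "scaffoldregen agent lattice",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {m + 1} {m + 1} {m + 1}",
        "ORIGIN 0 0 0",
        f"SPACING {lattice.spacing} {lattice.spacing} {lattice.spacing}",
        f"CELL_DATA {m**3}",
    ]
    for name, arr in (
        ("phenotype", lattice.phenotype),
        ("tissue", lattice.tissue),
        ("active", lattice.active.astype(np.uint8)),
    ):
        a = np.asarray(arr).reshape(m, m, m).transpose(2, 1, 0).reshape(-1)
        lines.append(f"SCALARS {name} int 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(str(int(v)) for v in a)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
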