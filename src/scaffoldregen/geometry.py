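"""Parametric cubic scaffold geometry.

A scaffold is a 3 mm cube pierced by three orthogonal families of square
pores (9 per axis, on a regular 3x3 grid with 1 mm centre spacing, centres
at 0.5/1.5/2.5 mm in the transverse axes).  Pores along x and y share one
size; pores along z have an independent size; both sizes range over
0.1-0.9 mm.  The union of the 27 square prisms is the regenerating-tissue
region; everything else is scaffold material.

This module generates, voxelizes and enumerates these designs; it is the
pipeline's only input generator (there is no external data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CUBE_SIDE = 3.0          # mm
PORE_CENTRES = (0.5, 1.5, 2.5)   # mm, per transverse axis
SIZE_MIN = 0.1           # mm
SIZE_MAX = 0.9           # mm

#: element material labels
SCAFFOLD = 0
TISSUE = 1


@dataclass(frozen=True)
class ScaffoldDesign:
    """Two free pore sizes; everything else about the cube is fixed.

    ``pore_size_x`` is shared by the pores along the x and y axes;
    ``pore_size_z`` applies to the pores along z.  Units are mm.
    """

    pore_size_x: float
    pore_size_z: float

    @property
    def pore_size_y(self) -> float:
        return self.pore_size_x

    def __post_init__(self) -> None:
        for name in ("pore_size_x", "pore_size_z"):
            v = getattr(self, name)
            if not (SIZE_MIN <= v <= SIZE_MAX):
                raise ValueError(
                    f"{name}={v!r} outside the admissible range "
                    f"[{SIZE_MIN}, {SIZE_MAX}] mm"
                )
        # With centres at 0.5/1.5/2.5 and sizes <= 0.9 every pore
        # cross-section lies strictly inside the cube face.


def make_design(pore_size_x: float, pore_size_z: float) -> ScaffoldDesign:
    """Validate and build a scaffold design (sizes in mm)."""
    return ScaffoldDesign(float(pore_size_x), float(pore_size_z))


def _axis_mask(coords: np.ndarray, width: float) -> np.ndarray:
    """True where a coordinate falls inside any of the three pore intervals.

    Intervals are half-open, ``[centre - w/2, centre + w/2)``, so that voxel
    counting does not depend on floating-point ties.
    """
    out = np.zeros(np.shape(coords), dtype=bool)
    for c in PORE_CENTRES:
        out |= (coords >= c - width / 2) & (coords < c + width / 2)
    return out


def pore_union_membership(point, design: ScaffoldDesign) -> bool:
    """True iff ``point`` (x, y, z in mm) lies inside the pore union.

    The union consists of 27 square prisms: the x-axis pores occupy
    ``y, z in I(pore_size_x)``, the y-axis pores ``x, z in I(pore_size_x)``
    and the z-axis pores ``x, y in I(pore_size_z)``, where ``I(w)`` is the
    union of three half-open intervals of width ``w`` centred at
    0.5/1.5/2.5 mm.
    """
    x, y, z = (float(v) for v in point)
    for v in (x, y, z):
        if not (0.0 <= v <= CUBE_SIDE):
            raise ValueError(f"point {point!r} outside the closed cube")
    px, pz = design.pore_size_x, design.pore_size_z
    in_x = bool(_axis_mask(y, px) and _axis_mask(z, px))
    in_y = bool(_axis_mask(x, px) and _axis_mask(z, px))
    in_z = bool(_axis_mask(x, pz) and _axis_mask(y, pz))
    return in_x or in_y or in_z


def _membership_grid(design: ScaffoldDesign, n: int) -> np.ndarray:
    """Boolean pore-union membership of the n^3 cell centroids, axes (x,y,z)."""
    h = CUBE_SIDE / n
    c = (np.arange(n) + 0.5) * h
    mx = _axis_mask(c, design.pore_size_x)
    mz = _axis_mask(c, design.pore_size_z)
    x_pores = mx[None, :, None] & mx[None, None, :]   # y and z in I(px)
    y_pores = mx[:, None, None] & mx[None, None, :]   # x and z in I(px)
    z_pores = mz[:, None, None] & mz[None, :, None]   # x and y in I(pz)
    return x_pores | y_pores | z_pores


@dataclass(frozen=True)
class VoxelGrid:
    """Structured hexahedral element grid with a binary material label.

    ``labels`` is an (n, n, n) uint8 array over (ix, iy, iz) with values
    :data:`SCAFFOLD` or :data:`TISSUE`; elements are cubes of side
    ``element_size`` mm.
    """

    element_size: float
    labels: np.ndarray
    design: ScaffoldDesign

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def n_elements(self) -> int:
        return int(self.labels.size)

    @property
    def tissue_mask(self) -> np.ndarray:
        """Flat (C-order) boolean mask of TISSUE elements."""
        return self.labels.reshape(-1) == TISSUE


def voxelize_design(design: ScaffoldDesign, element_size: float = 0.1) -> VoxelGrid:
    """Label each element TISSUE iff its centroid lies in the pore union.

    ``element_size`` must divide the 3 mm cube side exactly.
    """
    n = round(CUBE_SIDE / element_size)
    if n < 1 or abs(n * element_size - CUBE_SIDE) > 1e-9:
        raise ValueError(
            f"element_size={element_size!r} does not divide the "
            f"{CUBE_SIDE} mm cube side"
        )
    inside = _membership_grid(design, n)
    labels = np.where(inside, TISSUE, SCAFFOLD).astype(np.uint8)
    if not (inside.any() and (~inside).any()):
        raise ValueError(
            "degenerate voxelization: need at least one TISSUE and one "
            "SCAFFOLD element; refine element_size"
        )
    return VoxelGrid(element_size=float(element_size), labels=labels, design=design)


def compute_porosity(design: ScaffoldDesign, resolution: float = 0.025) -> float:
    """Pore-union volume fraction of the cube, from a fine voxel grid.

    The default 0.025 mm resolution aligns with every pore boundary of the
    0.05 mm-step design grid (sizes and centres are multiples of 0.05 and
    0.025 mm respectively), so the voxel count is exact for those designs.
    """
    n = round(CUBE_SIDE / resolution)
    if abs(n * resolution - CUBE_SIDE) > 1e-9:
        raise ValueError(f"resolution={resolution!r} does not divide the cube side")
    return float(_membership_grid(design, n).mean())


def enumerate_design_space(
    size_min: float = SIZE_MIN,
    size_max: float = SIZE_MAX,
    step: float = 0.05,
    porosity_min: float = 0.5,
    resolution: float = 0.025,
) -> pd.DataFrame:
    """Cartesian sweep over (pore_size_x, pore_size_z) with a porosity filter.

    Returns one row per candidate with columns ``pore_size_x``,
    ``pore_size_z``, ``porosity`` and ``admitted`` (porosity strictly
    greater than ``porosity_min``).  The defaults give the 17 x 17 = 289
    candidate grid of which 181 designs pass the >50% porosity filter.
    """
    k = round((size_max - size_min) / step)
    if abs(size_min + k * step - size_max) > 1e-9:
        raise ValueError("step does not divide the sampling range")
    sizes = np.round(size_min + step * np.arange(k + 1), 10)
    rows = []
    for px in sizes:
        for pz in sizes:
            design = make_design(px, pz)
            por = compute_porosity(design, resolution)
            rows.append((px, pz, por, por > porosity_min))
    return pd.DataFrame(
        rows, columns=["pore_size_x", "pore_size_z", "porosity", "admitted"]
    )


def export_design_table(table: pd.DataFrame, path) -> None:
    """Write the enumeration table as CSV (6 significant digits)."""
    table.to_csv(path, index=False, float_format="%.6g")
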