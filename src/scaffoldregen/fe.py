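"""Small-strain linear-elastic FE solver on the structured voxel grid.

Trilinear 8-node hexahedral elements on the voxelized scaffold, one
material per element.  The element stiffness splits into two
geometry-only matrices (volumetric and deviatoric parts of the isotropic
tensor), so assembly over heterogeneous materials is a vectorized linear
combination.  The default linear solver is conjugate gradients
preconditioned by a geometric multigrid V-cycle (Galerkin-coarsened
voxel hierarchy, Chebyshev-Jacobi smoothing, direct coarse solve),
converged to a relative residual below 1e-8 so downstream stimulus
classification is deterministic; small systems go straight to a sparse
direct factorization.

Conventions: 3-D arrays are indexed (ix, iy, iz) and flattened in C
order; nodes are numbered (ix*(n+1) + iy)*(n+1) + iz; the three dofs of
node ``p`` are ``3p, 3p+1, 3p+2`` for u_x, u_y, u_z.  Compression is
negative.  Units: mm, N, MPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import VoxelGrid

_DIRECT_DOF_LIMIT = 10_000   # below this, splu beats the multigrid setup

# local hex node order: a = 4*dx + 2*dy + dz over the unit-cube corners
_VERTS = np.array(
    [[dx, dy, dz] for dx in (0, 1) for dy in (0, 1) for dz in (0, 1)], dtype=float
)


@dataclass(frozen=True)
class MaterialField:
    """Per-element Young's modulus (MPa) and Poisson ratio, flat C order."""

    E: np.ndarray
    nu: np.ndarray

    def __post_init__(self) -> None:
        if self.E.shape != self.nu.shape:
            raise ValueError("E and nu must have identical shapes")
        if not (self.E > 0).all():
            raise ValueError("Young's modulus must be positive everywhere")
        if not ((self.nu >= 0) & (self.nu < 0.5)).all():
            raise ValueError("Poisson ratio must lie in [0, 0.5)")

    @property
    def lame(self) -> tuple[np.ndarray, np.ndarray]:
        lam = self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.E / (2 * (1 + self.nu))
        return lam, mu


def material_field_for_grid(
    grid: VoxelGrid,
    scaffold_E: float = 1000.0,
    scaffold_nu: float = 0.3,
    tissue_E: float = 0.2,
    tissue_nu: float = 0.167,
) -> MaterialField:
    """Binary scaffold/tissue material field (defaults: polymer-ceramic
    scaffold, granulation tissue)."""
    tis = grid.tissue_mask
    return MaterialField(
        E=np.where(tis, tissue_E, scaffold_E),
        nu=np.where(tis, tissue_nu, scaffold_nu),
    )


@dataclass(frozen=True)
class LoadCase:
    """Axial compression of the cube.

    ``force`` N total, applied as uniform traction on the top (z = 3 mm)
    face; ``surface`` selects whether the traction covers the whole face
    or only the scaffold-material facets.  The bottom face is fully fixed
    ("encastre") by default; ``constraint="roller"`` fixes only u_z at the
    bottom plus two in-plane pins (rigid-body control) and exists for
    uniform-state patch tests.
    """

    force: float = 15.0
    surface: str = "scaffold"        # "scaffold" | "full"
    constraint: str = "encastre"     # "encastre" | "roller"

    def __post_init__(self) -> None:
        if self.surface not in ("scaffold", "full"):
            raise ValueError(f"unknown load surface {self.surface!r}")
        if self.constraint not in ("encastre", "roller"):
            raise ValueError(f"unknown constraint {self.constraint!r}")


@dataclass
class MechField:
    """Per-element mechanical state from one solve (flat C order)."""

    sigma_h: np.ndarray       # hydrostatic stress, MPa (compression < 0)
    eps_min: np.ndarray       # minimal principal strain (dimensionless)
    eps_principal: np.ndarray  # all three strain eigenvalues, ascending
    element_volume: float     # mm^3, identical for all voxels


def hex_stiffness_parts(h: float) -> tuple[np.ndarray, np.ndarray]:
    """24x24 element matrices K_lam, K_mu with K_e = lam*K_lam + mu*K_mu.

    Exact 2x2x2 Gauss integration of the trilinear hexahedron of side
    ``h``; K_lam carries the volumetric (lambda I (x) I) part and K_mu the
    shear (2 mu I_sym) part of isotropic Hooke's law.
    """
    gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    K_lam = np.zeros((24, 24))
    K_mu = np.zeros((24, 24))
    D_lam = np.zeros((6, 6))
    D_lam[:3, :3] = 1.0
    D_mu = np.diag([2.0, 2.0, 2.0, 1.0, 1.0, 1.0])
    for gx in gauss:
        for gy in gauss:
            for gz in gauss:
                xi = (np.array([gx, gy, gz]) + 1) / 2  # in [0, 1]
                dN = np.empty((8, 3))
                for a, (vx, vy, vz) in enumerate(_VERTS):
                    sx = vx * xi[0] + (1 - vx) * (1 - xi[0])
                    sy = vy * xi[1] + (1 - vy) * (1 - xi[1])
                    sz = vz * xi[2] + (1 - vz) * (1 - xi[2])
                    dN[a] = [(2 * vx - 1) * sy * sz,
                             sx * (2 * vy - 1) * sz,
                             sx * sy * (2 * vz - 1)]
                dN /= h
                B = _strain_matrix(dN)
                w = (h / 2) ** 3
                K_lam += w * B.T @ D_lam @ B
                K_mu += w * B.T @ D_mu @ B
    return K_lam, K_mu


def _strain_matrix(dN: np.ndarray) -> np.ndarray:
    """Voigt strain-displacement matrix (6 x 24) from shape gradients."""
    B = np.zeros((6, 24))
    for a in range(8):
        bx, by, bz = dN[a]
        B[0, 3 * a] = bx
        B[1, 3 * a + 1] = by
        B[2, 3 * a + 2] = bz
        B[3, 3 * a] = by
        B[3, 3 * a + 1] = bx
        B[4, 3 * a + 1] = bz
        B[4, 3 * a + 2] = by
        B[5, 3 * a] = bz
        B[5, 3 * a + 2] = bx
    return B


class _MeshCache:
    """Structure shared by every solve on an n^3 voxel grid."""

    def __init__(self, n: int, h: float):
        self.n, self.h = n, h
        nn = n + 1
        self.nn = nn
        self.ndof = 3 * nn**3
        ix, iy, iz = np.meshgrid(
            np.arange(n), np.arange(n), np.arange(n), indexing="ij"
        )
        corner = (ix.reshape(-1) * nn + iy.reshape(-1)) * nn + iz.reshape(-1)
        offs = np.array(
            [(dx * nn + dy) * nn + dz for dx in (0, 1) for dy in (0, 1) for dz in (0, 1)]
        )
        self.enodes = (corner[:, None] + offs[None, :]).astype(np.int64)  # (ne, 8)
        self.edofs = (
            3 * self.enodes[:, :, None] + np.arange(3)[None, None, :]
        ).reshape(-1, 24).astype(np.int32)
        shape = (n**3, 24, 24)
        self.rows = np.broadcast_to(self.edofs[:, :, None], shape).reshape(-1)
        self.cols = np.broadcast_to(self.edofs[:, None, :], shape).reshape(-1)
        self.iz_elem = iz.reshape(-1)
        self.K_lam, self.K_mu = hex_stiffness_parts(h)
        self._csr_pattern = None   # built lazily on first assembly
        # centroid shape-function gradients for strain recovery
        self.dN_centroid = (2 * _VERTS - 1) * 0.25 / h
        node = np.arange(nn**3)
        self.node_z = node % nn
        self.node_y = (node // nn) % nn
        self.node_x = node // (nn * nn)


_mesh_cache: dict[int, _MeshCache] = {}


def _mesh(grid: VoxelGrid) -> _MeshCache:
    key = grid.n
    m = _mesh_cache.get(key)
    if m is None or abs(m.h - grid.element_size) > 1e-12:
        m = _MeshCache(grid.n, grid.element_size)
        _mesh_cache[key] = m
    return m


def assemble_stiffness(grid: VoxelGrid, materials: MaterialField) -> sp.csr_matrix:
    """Global stiffness K (no boundary conditions applied).

    The scatter pattern (COO entry -> CSR slot) depends only on the grid,
    so it is computed once per mesh and reused; per-call work is a gather
    plus one weighted bincount over the element contributions.
    """
    m = _mesh(grid)
    if materials.E.size != grid.n_elements:
        raise ValueError("materials and grid have different element counts")
    lam, mu = materials.lame
    data = (
        lam[:, None] * m.K_lam.reshape(-1)[None, :]
        + mu[:, None] * m.K_mu.reshape(-1)[None, :]
    ).reshape(-1)
    if m._csr_pattern is None:
        order = np.lexsort((m.cols, m.rows)).astype(np.int32)
        rs, cs = m.rows[order], m.cols[order]
        new_slot = np.empty(order.size, dtype=bool)
        new_slot[0] = True
        new_slot[1:] = (rs[1:] != rs[:-1]) | (cs[1:] != cs[:-1])
        slot = (np.cumsum(new_slot) - 1).astype(np.int32)
        indices = cs[new_slot].astype(np.int32)
        counts = np.bincount(rs[new_slot], minlength=m.ndof)
        indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int32)
        m._csr_pattern = (order, slot, indices, indptr, int(slot[-1]) + 1)
    order, slot, indices, indptr, nnz = m._csr_pattern
    vals = np.bincount(slot, weights=data[order], minlength=nnz)
    return sp.csr_matrix((vals, indices, indptr), shape=(m.ndof, m.ndof))


def _fixed_dofs(grid: VoxelGrid, constraint: str) -> np.ndarray:
    """Boolean mask of constrained dofs for the requested support."""
    m = _mesh(grid)
    bottom = np.where(m.node_z == 0)[0]
    fixed = np.zeros(m.ndof, dtype=bool)
    if constraint == "encastre":
        for d in range(3):
            fixed[3 * bottom + d] = True
    elif constraint == "roller":
        fixed[3 * bottom + 2] = True
        nn = m.nn
        origin = 0                      # node (0, 0, 0)
        xend = (nn - 1) * nn * nn       # node (n, 0, 0)
        fixed[3 * origin] = True        # u_x
        fixed[3 * origin + 1] = True    # u_y
        fixed[3 * xend + 1] = True      # u_y: blocks rotation about z
    elif constraint == "pins":
        # minimal rigid-body control for all-face pressure tests
        nn = m.nn
        origin = 0
        xend = (nn - 1) * nn * nn
        yend = (nn - 1) * nn
        fixed[3 * origin:3 * origin + 3] = True
        fixed[3 * xend + 1] = True
        fixed[3 * xend + 2] = True
        fixed[3 * yend + 2] = True
    else:
        raise ValueError(f"unknown constraint {constraint!r}")
    return fixed


def top_load_vector(grid: VoxelGrid, load: LoadCase) -> np.ndarray:
    """Consistent nodal forces for uniform traction on the selected top facets."""
    m = _mesh(grid)
    top_elems = np.where(m.iz_elem == m.n - 1)[0]
    if load.surface == "scaffold":
        sel = top_elems[~grid.tissue_mask[top_elems]]
    else:
        sel = top_elems
    if sel.size == 0:
        raise ValueError(
            "empty loaded surface: no top-face facets match "
            f"surface={load.surface!r} for this design"
        )
    area = sel.size * m.h**2
    traction = load.force / area          # MPa, applied downward
    f = np.zeros(m.ndof)
    # top facet of a hex = local nodes with dz = 1: a in {1, 3, 5, 7}
    for a in (1, 3, 5, 7):
        np.add.at(f, 3 * m.enodes[sel, a] + 2, -traction * m.h**2 / 4)
    return f


def face_pressure_vector(grid: VoxelGrid, pressure: float) -> np.ndarray:
    """Consistent nodal forces for uniform pressure on all six cube faces."""
    m = _mesh(grid)
    n = m.n
    f = np.zeros(m.ndof)
    per_node = pressure * m.h**2 / 4
    ix = np.arange(n**3) // (n * n)
    iy = (np.arange(n**3) // n) % n
    iz = m.iz_elem
    faces = [
        (iz == n - 1, (1, 3, 5, 7), 2, -1),   # top, -z traction
        (iz == 0, (0, 2, 4, 6), 2, +1),       # bottom, +z
        (ix == n - 1, (4, 5, 6, 7), 0, -1),   # +x face
        (ix == 0, (0, 1, 2, 3), 0, +1),
        (iy == n - 1, (2, 3, 6, 7), 1, -1),   # +y face
        (iy == 0, (0, 1, 4, 5), 1, +1),
    ]
    for mask, locals_, dof, sign in faces:
        sel = np.where(mask)[0]
        for a in locals_:
            np.add.at(f, 3 * m.enodes[sel, a] + dof, sign * per_node)
    return f


# ---------------------------------------------------------------------------
# geometric multigrid preconditioner
# ---------------------------------------------------------------------------

def _interp1d(nf: int, nc: int) -> sp.csr_matrix:
    """1-D linear interpolation from nc+1 coarse to nf+1 fine nodes."""
    r = nf // nc
    rows, cols, vals = [], [], []
    for i in range(nf + 1):
        x = i / r
        j = int(np.floor(x))
        w = x - j
        if j >= nc:
            j, w = nc - 1, 1.0
        if w == 0.0:
            rows.append(i)
            cols.append(j)
            vals.append(1.0)
        else:
            rows += [i, i]
            cols += [j, j + 1]
            vals += [1.0 - w, w]
    return sp.coo_matrix((vals, (rows, cols)), shape=(nf + 1, nc + 1)).tocsr()


def _coarsen_sequence(n: int) -> list[tuple[int, int]]:
    seq = []
    while n > 5:
        if n % 2 == 0:
            nc = n // 2
        elif n % 3 == 0:
            nc = n // 3
        else:
            break
        seq.append((n, nc))
        n = nc
    return seq


_prolong_cache: dict[tuple[int, int], sp.csr_matrix] = {}


def _prolongation(nf: int, nc: int) -> sp.csr_matrix:
    P = _prolong_cache.get((nf, nc))
    if P is None:
        P1 = _interp1d(nf, nc)
        P = sp.kron(sp.kron(P1, P1), sp.kron(P1, sp.identity(3))).tocsr()
        _prolong_cache[(nf, nc)] = P
    return P


class MultigridPreconditioner:
    """V-cycle on Galerkin-coarsened operators, Chebyshev-Jacobi smoothing."""

    def __init__(self, A: sp.csr_matrix, n: int, smooth_iters: int = 3):
        self.smooth_iters = smooth_iters
        self.levels: list[tuple[sp.csr_matrix, sp.csr_matrix, np.ndarray, float]] = []
        for nf, nc in _coarsen_sequence(n):
            P = _prolongation(nf, nc)
            d = A.diagonal().copy()
            d[d == 0] = 1.0
            lmax = self._estimate_lmax(A, d)
            self.levels.append((A, P, d, lmax))
            A = (P.T @ A @ P).tocsr()
        self.coarse_lu = spla.splu(A.tocsc())

    @staticmethod
    def _estimate_lmax(A: sp.csr_matrix, d: np.ndarray) -> float:
        rng = np.random.default_rng(0)
        x = rng.standard_normal(A.shape[0])
        nrm = 1.0
        for _ in range(10):
            x = A @ (x / d)
            nrm = np.linalg.norm(x)
            x /= nrm
        return 1.1 * nrm

    def _smooth(self, A, d, lmax, x, b):
        lmin = 0.06 * lmax
        theta = (lmax + lmin) / 2
        delta = (lmax - lmin) / 2
        sigma = theta / delta
        rho = 1 / sigma
        r = b - A @ x
        p = (r / d) / theta
        x = x + p
        for _ in range(self.smooth_iters - 1):
            rho_new = 1 / (2 * sigma - rho)
            r = b - A @ x
            p = rho_new * rho * p + (2 * rho_new / delta) * (r / d)
            rho = rho_new
            x = x + p
        return x

    def _vcycle(self, level: int, b: np.ndarray) -> np.ndarray:
        if level == len(self.levels):
            return self.coarse_lu.solve(b)
        A, P, d, lmax = self.levels[level]
        x = self._smooth(A, d, lmax, np.zeros_like(b), b)
        x = x + P @ self._vcycle(level + 1, P.T @ (b - A @ x))
        return self._smooth(A, d, lmax, x, b)

    def __call__(self, b: np.ndarray) -> np.ndarray:
        return self._vcycle(0, b)


class SingularSystemError(RuntimeError):
    pass


def _solve_system(
    A_bc: sp.csr_matrix,
    f: np.ndarray,
    n: int,
    rtol: float = 1e-8,
    x0: np.ndarray | None = None,
    precond: MultigridPreconditioner | None = None,
) -> tuple[np.ndarray, MultigridPreconditioner | None]:
    """Solve the Dirichlet-eliminated system; returns (u, preconditioner)."""
    if A_bc.shape[0] <= _DIRECT_DOF_LIMIT or not _coarsen_sequence(n):
        u = spla.splu(A_bc.tocsc()).solve(f)
        if not np.isfinite(u).all():
            raise SingularSystemError("direct solve produced non-finite values")
        return u, None
    if precond is None:
        precond = MultigridPreconditioner(A_bc, n)
    M = spla.LinearOperator(A_bc.shape, precond)
    u, info = spla.cg(A_bc, f, x0=x0, M=M, rtol=rtol, atol=0.0, maxiter=2000)
    if info != 0:
        raise SingularSystemError(
            f"PCG failed to reach relative residual {rtol:g} (info={info}); "
            "the system may be unconstrained"
        )
    return u, precond


def apply_dirichlet(
    K: sp.csr_matrix, f: np.ndarray, fixed: np.ndarray
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Symmetric elimination of homogeneous Dirichlet dofs (identity rows)."""
    keep = sp.diags((~fixed).astype(float))
    A = (keep @ K @ keep + sp.diags(fixed.astype(float))).tocsr()
    fb = f.copy()
    fb[fixed] = 0.0
    return A, fb


def solve_static(
    grid: VoxelGrid,
    materials: MaterialField,
    load: LoadCase,
    x0: np.ndarray | None = None,
    precond: MultigridPreconditioner | None = None,
    return_precond: bool = False,
):
    """Nodal displacements (mm, flat ndof vector) for one static solve."""
    K = assemble_stiffness(grid, materials)
    f = top_load_vector(grid, load)
    fixed = _fixed_dofs(grid, load.constraint)
    A, fb = apply_dirichlet(K, f, fixed)
    u, pc = _solve_system(A, fb, grid.n, x0=x0, precond=precond)
    if return_precond:
        return u, pc
    return u


def reaction_forces(
    grid: VoxelGrid, materials: MaterialField, load: LoadCase, u: np.ndarray
) -> np.ndarray:
    """Reactions K u - f at the constrained dofs (zero elsewhere)."""
    K = assemble_stiffness(grid, materials)
    f = top_load_vector(grid, load)
    fixed = _fixed_dofs(grid, load.constraint)
    r = K @ u - f
    r[~fixed] = 0.0
    return r


def element_mechanics(
    u: np.ndarray, materials: MaterialField, grid: VoxelGrid
) -> MechField:
    """Centroid strain/stress measures per element.

    The strain tensor is the symmetric gradient of the trilinear
    displacement field evaluated once at the element centroid; stress
    follows from isotropic Hooke's law with the element's constants.
    """
    m = _mesh(grid)
    ne = grid.n_elements
    ue = u[(3 * m.enodes[:, :, None] + np.arange(3))]        # (ne, 8, 3)
    G = np.einsum("eai,aj->eij", ue, m.dN_centroid)          # du_i/dx_j
    eps = 0.5 * (G + G.transpose(0, 2, 1))
    lam, mu = materials.lame
    tr = np.trace(eps, axis1=1, axis2=2)
    sigma_h = (lam + 2.0 * mu / 3.0) * tr                    # tr(sigma)/3
    eigs = np.linalg.eigvalsh(eps)                           # ascending
    return MechField(
        sigma_h=sigma_h,
        eps_min=eigs[:, 0],
        eps_principal=eigs,
        element_volume=m.h**3,
    )
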