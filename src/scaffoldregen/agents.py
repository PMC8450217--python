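"""Lattice agent-based model of the cell populations inside the pores.

Cells live on a cubic site lattice spanning the cube (default 20 um
spacing, i.e. 5x5x5 sites per 0.1 mm FE element).  A site is active when
its containing element is regenerating tissue; inactive (scaffold) sites
never hold cells or tissue.  Each site carries at most one cell --
progenitor, fibroblast, chondrocyte or osteoblast -- and one deposited
tissue type.  Progenitors are seeded on the top and bottom tissue
surfaces (bone-marrow-like cell sources), migrate as an unbiased
6-neighbour random walk, and differentiate under the local mechanical
stimulus; differentiated cells deposit their tissue in place, proliferate
when the stimulus favours them and undergo apoptosis otherwise.

The per-day update order is migration -> differentiation ->
proliferation/apoptosis.  All kernels are compiled with numba and draw
their randomness from an explicit per-call seed, so a full day update is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .geometry import VoxelGrid
from .mechanoreg import Tissue, TissueClass

# cell phenotype codes (uint8)
EMPTY = 0
PROGENITOR = 1
FIBROBLAST = 2
CHONDROCYTE = 3
OSTEOBLAST = 4

PHENOTYPE_NAMES = {
    EMPTY: "empty",
    PROGENITOR: "progenitor",
    FIBROBLAST: "fibroblast",
    CHONDROCYTE: "chondrocyte",
    OSTEOBLAST: "osteoblast",
}

#: phenotype favoured by each stimulus class (resorption favours none)
_PHENO_FOR_CLASS = np.array([0, OSTEOBLAST, CHONDROCYTE, FIBROBLAST], dtype=np.uint8)

#: tissue deposited by each phenotype (progenitors deposit granulation,
#: i.e. leave the initial filling unchanged)
_TISSUE_FOR_PHENO = np.array(
    [0, int(Tissue.GRANULATION), int(Tissue.FIBROUS_TISSUE),
     int(Tissue.CARTILAGE), int(Tissue.BONE)],
    dtype=np.uint8,
)


@dataclass(frozen=True)
class CellRates:
    """Daily probabilities of the stochastic cell processes.

    Values follow the fracture-healing model lineage this simulator
    derives from; they are calibration parameters, exposed through the
    run configuration.  ``migration_speed`` is in um/h and applies to
    progenitors only.
    """

    proliferation: dict[int, float] = field(
        default_factory=lambda: {
            PROGENITOR: 0.60,
            FIBROBLAST: 0.55,
            CHONDROCYTE: 0.20,
            OSTEOBLAST: 0.30,
        }
    )
    differentiation: float = 0.30
    apoptosis: float = 0.05
    migration_speed: float = 30.0

    def __post_init__(self) -> None:
        probs = [*self.proliferation.values(), self.differentiation, self.apoptosis]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all rates must be probabilities in [0, 1]")

    @property
    def proliferation_array(self) -> np.ndarray:
        out = np.zeros(5)
        for pheno, p in self.proliferation.items():
            out[pheno] = p
        return out


@dataclass
class AgentLattice:
    """Mutable state of the cell/tissue lattice.

    Flat arrays of length m^3 in C order over (sx, sy, sz); ``phenotype``
    holds the cell codes above, ``tissue`` the deposited Tissue values,
    ``site_elem`` the flat index of the FE element containing each site.
    """

    m: int
    spacing: float
    active: np.ndarray
    site_elem: np.ndarray
    phenotype: np.ndarray
    tissue: np.ndarray

    @classmethod
    def from_grid(cls, grid: VoxelGrid, sites_per_element: int = 5) -> "AgentLattice":
        k = int(sites_per_element)
        if k < 1:
            raise ValueError("sites_per_element must be >= 1")
        m = grid.n * k
        s = np.arange(m)
        e = s // k
        # element flat index of each site, via broadcasting over (sx, sy, sz)
        n = grid.n
        site_elem = (
            (e[:, None, None] * n + e[None, :, None]) * n + e[None, None, :]
        ).astype(np.int32).reshape(-1)
        active = grid.tissue_mask[site_elem]
        return cls(
            m=m,
            spacing=grid.element_size / k,
            active=active,
            site_elem=site_elem,
            phenotype=np.zeros(m**3, dtype=np.uint8),
            tissue=np.zeros(m**3, dtype=np.uint8),   # GRANULATION everywhere
        )

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def cell_census(self) -> dict[str, int]:
        counts = np.bincount(self.phenotype[self.active], minlength=5)
        return {PHENOTYPE_NAMES[i]: int(counts[i]) for i in range(5)}

    def surface_sites(self) -> np.ndarray:
        """Active sites in the top and bottom lattice layers (flat indices)."""
        m = self.m
        sz = np.arange(m**3) % m
        layer = (sz == 0) | (sz == m - 1)
        return np.where(layer & self.active)[0]

    def check_invariants(self) -> None:
        if (self.phenotype[~self.active] != 0).any():
            raise AssertionError("cell on an inactive (scaffold) site")
        if (self.tissue[~self.active] != 0).any():
            raise AssertionError("deposited tissue on an inactive site")


def jumps_per_day(speed_um_h: float, spacing_mm: float) -> int:
    """Single-site move attempts per day at the given migration speed."""
    return round(speed_um_h * 24.0 / (spacing_mm * 1000.0))


def seed_initial_cells(
    lattice: AgentLattice, occupancy: float = 0.30, rng: np.random.Generator | None = None
) -> AgentLattice:
    """Place progenitors on a random subset of the top/bottom active sites."""
    if not (0.0 <= occupancy <= 1.0):
        raise ValueError("occupancy must lie in [0, 1]")
    if (lattice.phenotype != 0).any():
        raise ValueError("lattice already seeded")
    rng = np.random.default_rng() if rng is None else rng
    surface = lattice.surface_sites()
    if surface.size == 0:
        raise ValueError("no active surface sites: degenerate design")
    count = round(occupancy * surface.size)
    chosen = rng.choice(surface, size=count, replace=False)
    lattice.phenotype[chosen] = PROGENITOR
    return lattice


@njit(cache=True)
def _shuffle(order, n):  # Fisher-Yates, numba-friendly
    for i in range(n - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = order[i]
        order[i] = order[j]
        order[j] = tmp


@njit(cache=True)
def _migrate_kernel(phen, active, pos, m, sweeps, seed):
    np.random.seed(seed)
    npg = pos.size
    order = np.arange(npg)
    for _ in range(sweeps):
        _shuffle(order, npg)
        for oi in range(npg):
            i = order[oi]
            s = pos[i]
            d = np.random.randint(0, 6)
            sz = s % m
            sy = (s // m) % m
            sx = s // (m * m)
            if d == 0:
                sx += 1
            elif d == 1:
                sx -= 1
            elif d == 2:
                sy += 1
            elif d == 3:
                sy -= 1
            elif d == 4:
                sz += 1
            else:
                sz -= 1
            if sx < 0 or sx >= m or sy < 0 or sy >= m or sz < 0 or sz >= m:
                continue
            t = (sx * m + sy) * m + sz
            if active[t] and phen[t] == EMPTY:
                phen[t] = PROGENITOR
                phen[s] = EMPTY
                pos[i] = t


def migrate_cells(
    lattice: AgentLattice, jumps: int, seed: int, return_positions: bool = False
):
    """Random-walk migration of all progenitors: ``jumps`` sweeps, one
    attempted 6-neighbour move per progenitor per sweep, rejection at
    occupied/inactive/out-of-lattice targets, fresh random cell order
    every sweep.  With ``return_positions`` the final site of each walker
    is returned, ordered by its starting site (ascending)."""
    pos = np.where(lattice.phenotype == PROGENITOR)[0].astype(np.int64)
    if pos.size and jumps:
        _migrate_kernel(
            lattice.phenotype, lattice.active, pos, lattice.m, jumps, np.uint32(seed)
        )
    if return_positions:
        return lattice, pos
    return lattice


@njit(cache=True)
def _fates_kernel(phen, site_class, m, pheno_for_class, p_diff, prolif, p_apop,
                  active, seed):
    np.random.seed(seed)
    cells = np.where(phen > 0)[0]
    nc = cells.size
    # differentiation: progenitors adopt the stimulus-matched phenotype
    for idx in range(nc):
        s = cells[idx]
        if phen[s] != PROGENITOR:
            continue
        c = site_class[s]
        if c >= 1 and np.random.random() < p_diff:
            phen[s] = pheno_for_class[c]
    # proliferation / apoptosis, in random order (daughters act next day)
    order = np.arange(nc)
    _shuffle(order, nc)
    for oi in range(nc):
        s = cells[order[oi]]
        p = phen[s]
        if p == EMPTY:
            continue
        c = site_class[s]
        if c == 0:  # resorption: apoptosis of every phenotype
            if np.random.random() < p_apop:
                phen[s] = EMPTY
            continue
        favoured = pheno_for_class[c]
        if p == PROGENITOR or p == favoured:
            if np.random.random() < prolif[p]:
                # uniform choice among empty active 6-neighbours
                sz = s % m
                sy = (s // m) % m
                sx = s // (m * m)
                count = 0
                targets = np.empty(6, dtype=np.int64)
                for d in range(6):
                    tx, ty, tz = sx, sy, sz
                    if d == 0:
                        tx += 1
                    elif d == 1:
                        tx -= 1
                    elif d == 2:
                        ty += 1
                    elif d == 3:
                        ty -= 1
                    elif d == 4:
                        tz += 1
                    else:
                        tz -= 1
                    if tx < 0 or tx >= m or ty < 0 or ty >= m or tz < 0 or tz >= m:
                        continue
                    t = (tx * m + ty) * m + tz
                    if active[t] and phen[t] == EMPTY:
                        targets[count] = t
                        count += 1
                if count > 0:
                    phen[targets[np.random.randint(0, count)]] = p
        else:  # differentiated phenotype mismatching the stimulus
            if np.random.random() < p_apop:
                phen[s] = EMPTY


def apply_cell_fates(
    lattice: AgentLattice,
    element_classes: np.ndarray,
    rates: CellRates,
    seed: int,
) -> AgentLattice:
    """One day of differentiation, proliferation, apoptosis and deposition.

    ``element_classes`` holds one TissueClass value per FE element (flat).
    Progenitors differentiate toward the class of their containing element
    (BONE -> osteoblast, CARTILAGE -> chondrocyte, FIBROUS -> fibroblast);
    progenitors and the class-matched phenotype proliferate into a random
    empty active neighbour; mismatched differentiated phenotypes apoptose;
    under RESORPTION every cell apoptoses.  Differentiated cells then
    deposit their tissue at their site; deposited bone is never
    overwritten by other tissue (only elementwise resorption removes it).
    """
    if element_classes.size <= int(lattice.site_elem.max()):
        raise ValueError("element_classes does not cover every lattice site")
    site_class = element_classes.astype(np.uint8)[lattice.site_elem]
    _fates_kernel(
        lattice.phenotype,
        site_class,
        lattice.m,
        _PHENO_FOR_CLASS,
        rates.differentiation,
        rates.proliferation_array,
        rates.apoptosis,
        lattice.active,
        np.uint32(seed),
    )
    deposit_tissue(lattice)
    return lattice


def deposit_tissue(lattice: AgentLattice) -> None:
    """Differentiated cells overwrite their site's tissue (bone persists)."""
    diff = lattice.phenotype >= FIBROBLAST
    writable = diff & (lattice.tissue != int(Tissue.BONE))
    lattice.tissue[writable] = _TISSUE_FOR_PHENO[lattice.phenotype[writable]]


def resorb_elements(lattice: AgentLattice, element_classes: np.ndarray) -> None:
    """Reset deposited tissue to granulation in RESORPTION-classified
    elements; the only pathway that removes deposited bone."""
    resorbing = element_classes.astype(np.uint8)[lattice.site_elem] == int(
        TissueClass.RESORPTION
    )
    lattice.tissue[resorbing & lattice.active] = int(Tissue.GRANULATION)
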