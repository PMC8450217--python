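"""Agent lattice: seeding, migration statistics, stochastic cell fates."""

import numpy as np
import pytest

from scaffoldregen import (
    CellRates,
    TissueClass,
    make_design,
    voxelize_design,
)
from scaffoldregen.agents import (
    AgentLattice,
    CHONDROCYTE,
    EMPTY,
    FIBROBLAST,
    OSTEOBLAST,
    PROGENITOR,
    apply_cell_fates,
    deposit_tissue,
    jumps_per_day,
    migrate_cells,
    resorb_elements,
    seed_initial_cells,
)
from scaffoldregen.geometry import pore_union_membership
from scaffoldregen.mechanoreg import Tissue


def free_lattice(m: int) -> AgentLattice:
    """A fully active lattice with a single dummy element (open space)."""
    return AgentLattice(
        m=m,
        spacing=0.02,
        active=np.ones(m**3, dtype=bool),
        site_elem=np.zeros(m**3, dtype=np.int32),
        phenotype=np.zeros(m**3, dtype=np.uint8),
        tissue=np.zeros(m**3, dtype=np.uint8),
    )


@pytest.fixture(scope="module")
def pored_lattice():
    grid = voxelize_design(make_design(0.7, 0.8), 0.15)
    return AgentLattice.from_grid(grid, sites_per_element=5), grid


class TestLatticeConstruction:
    def test_sites_per_element_mapping(self, pored_lattice):
        lat, grid = pored_lattice
        assert lat.m == grid.n * 5
        counts = np.bincount(lat.site_elem, minlength=grid.n_elements)
        assert (counts == 125).all()

    def test_activity_follows_element_labels(self, pored_lattice):
        lat, grid = pored_lattice
        assert lat.n_active == 125 * int(grid.tissue_mask.sum())

    def test_spacing_is_nominal_20um_at_default_resolution(self):
        grid = voxelize_design(make_design(0.5, 0.5), 0.1)
        lat = AgentLattice.from_grid(grid, 5)
        assert lat.m == 150
        assert lat.spacing == pytest.approx(0.02)
        assert jumps_per_day(30.0, lat.spacing) == 36


class TestSeeding:
    def test_zero_and_full_occupancy(self, pored_lattice, rng):
        lat, _ = pored_lattice
        empty = AgentLattice(lat.m, lat.spacing, lat.active, lat.site_elem,
                             np.zeros_like(lat.phenotype), np.zeros_like(lat.tissue))
        seed_initial_cells(empty, 0.0, rng)
        assert empty.cell_census()["progenitor"] == 0
        seed_initial_cells(empty, 1.0, rng)
        assert empty.cell_census()["progenitor"] == empty.surface_sites().size

    def test_seeded_count_and_interior_empty(self, rng):
        design = make_design(0.7, 0.8)
        grid = voxelize_design(design, 0.15)
        lat = AgentLattice.from_grid(grid, 5)
        seed_initial_cells(lat, 0.30, rng)
        surface = lat.surface_sites()
        # independent surface-site count: a z-extreme element is tissue iff
        # its centroid lies in the pore union, and contributes 5x5 sites
        h = grid.element_size
        ce = (np.arange(grid.n) + 0.5) * h
        tissue_cols = sum(
            pore_union_membership((x, y, h / 2), design) for x in ce for y in ce
        )
        assert surface.size == 2 * 25 * tissue_cols
        assert lat.cell_census()["progenitor"] == round(0.3 * surface.size)
        interior = lat.active.copy()
        interior[surface] = False
        assert (lat.phenotype[interior] == EMPTY).all()
        lat.check_invariants()

    def test_reseeding_rejected(self, rng):
        grid = voxelize_design(make_design(0.5, 0.5), 0.3)
        lat = AgentLattice.from_grid(grid, 3)
        seed_initial_cells(lat, 0.3, rng)
        with pytest.raises(ValueError):
            seed_initial_cells(lat, 0.3, rng)


class TestMigration:
    def test_trapped_cell_never_moves(self):
        lat = free_lattice(3)
        lat.active[:] = False
        centre = (1 * 3 + 1) * 3 + 1
        lat.active[centre] = True
        lat.phenotype[centre] = PROGENITOR
        migrate_cells(lat, jumps=50, seed=7)
        assert lat.phenotype[centre] == PROGENITOR
        assert lat.cell_census()["progenitor"] == 1

    def test_cell_count_conserved(self, rng):
        lat = free_lattice(20)
        sites = rng.choice(20**3, size=500, replace=False)
        lat.phenotype[sites] = PROGENITOR
        migrate_cells(lat, jumps=36, seed=11)
        assert (lat.phenotype == PROGENITOR).sum() == 500

    def test_unbiased_random_walk_msd(self):
        """After one day (36 attempted jumps) the mean displacement is ~0 and
        the mean squared displacement ~36 lattice units (dilute walkers)."""
        m, n_cells, jumps = 220, 10_000, 36
        lat = free_lattice(m)
        rng = np.random.default_rng(42)
        lo, hi = 40, m - 40
        span = hi - lo
        flat = rng.choice(span**3, size=n_cells, replace=False)
        xs = lo + flat // (span * span)
        ys = lo + (flat // span) % span
        zs = lo + flat % span
        start = np.sort((xs * m + ys) * m + zs)
        lat.phenotype[start] = PROGENITOR
        _, end = migrate_cells(lat, jumps=jumps, seed=3, return_positions=True)
        sx, sy, sz = start // (m * m), (start // m) % m, start % m
        ex, ey, ez = end // (m * m), (end // m) % m, end % m
        dx, dy, dz = ex - sx, ey - sy, ez - sz
        for d in (dx, dy, dz):
            assert abs(d.mean()) < 3 * np.sqrt(jumps / 3 / n_cells)
        msd = (dx**2 + dy**2 + dz**2).mean()
        # MC 3-sigma ~ 0.9 lattice units, plus a small collision allowance
        assert msd == pytest.approx(jumps, abs=1.5)


def uniform_class_field(c: TissueClass) -> np.ndarray:
    return np.full(1, int(c), dtype=np.uint8)


class TestCellFates:
    def test_forced_differentiation(self):
        lat = free_lattice(5)
        lat.phenotype[62] = PROGENITOR
        rates = CellRates(differentiation=1.0, apoptosis=0.0,
                          proliferation={PROGENITOR: 0.0, FIBROBLAST: 0.0,
                                         CHONDROCYTE: 0.0, OSTEOBLAST: 0.0})
        apply_cell_fates(lat, uniform_class_field(TissueClass.BONE), rates, 1)
        assert lat.phenotype[62] == OSTEOBLAST
        assert lat.tissue[62] == int(Tissue.BONE)

    def test_differentiation_fraction_binomial(self):
        lat = free_lattice(40)
        rng = np.random.default_rng(0)
        sites = rng.choice(40**3, size=10_000, replace=False)
        lat.phenotype[sites] = PROGENITOR
        p = 0.3
        rates = CellRates(differentiation=p, apoptosis=0.0,
                          proliferation={PROGENITOR: 0.0, FIBROBLAST: 0.0,
                                         CHONDROCYTE: 0.0, OSTEOBLAST: 0.0})
        apply_cell_fates(lat, uniform_class_field(TissueClass.BONE), rates, 5)
        frac = (lat.phenotype[sites] == OSTEOBLAST).mean()
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 10_000)

    def test_count_constant_without_proliferation_and_apoptosis(self):
        lat = free_lattice(10)
        rng = np.random.default_rng(1)
        sites = rng.choice(10**3, size=200, replace=False)
        lat.phenotype[sites] = PROGENITOR
        rates = CellRates(differentiation=0.3, apoptosis=0.0,
                          proliferation={PROGENITOR: 0.0, FIBROBLAST: 0.0,
                                         CHONDROCYTE: 0.0, OSTEOBLAST: 0.0})
        for day in range(5):
            migrate_cells(lat, 36, seed=day)
            apply_cell_fates(lat, uniform_class_field(TissueClass.FIBROUS),
                             rates, seed=100 + day)
        assert (lat.phenotype != EMPTY).sum() == 200

    def test_no_retrodifferentiation_ever(self):
        lat = free_lattice(12)
        rng = np.random.default_rng(2)
        sites = rng.choice(12**3, size=400, replace=False)
        lat.phenotype[sites] = PROGENITOR
        classes = np.array([int(TissueClass.CARTILAGE)], dtype=np.uint8)
        rates = CellRates()
        for day in range(8):
            before = lat.phenotype.copy()
            apply_cell_fates(lat, classes, rates, seed=day)
            was_diff = before >= FIBROBLAST
            still_alive = lat.phenotype[was_diff] != EMPTY
            assert (
                lat.phenotype[was_diff][still_alive]
                == before[was_diff][still_alive]
            ).all()

    def test_resorption_kills_all_phenotypes(self):
        lat = free_lattice(6)
        lat.phenotype[:4] = [PROGENITOR, FIBROBLAST, CHONDROCYTE, OSTEOBLAST]
        rates = CellRates(apoptosis=1.0)
        apply_cell_fates(lat, uniform_class_field(TissueClass.RESORPTION), rates, 9)
        assert (lat.phenotype == EMPTY).all()

    def test_apoptosis_only_hits_mismatched(self):
        lat = free_lattice(6)
        lat.phenotype[0] = OSTEOBLAST   # matched under BONE
        lat.phenotype[5] = FIBROBLAST   # mismatched
        rates = CellRates(apoptosis=1.0, differentiation=0.0,
                          proliferation={PROGENITOR: 0.0, FIBROBLAST: 0.0,
                                         CHONDROCYTE: 0.0, OSTEOBLAST: 0.0})
        apply_cell_fates(lat, uniform_class_field(TissueClass.BONE), rates, 4)
        assert lat.phenotype[0] == OSTEOBLAST
        assert lat.phenotype[5] == EMPTY

    def test_proliferation_fills_neighbours_and_respects_occupancy(self):
        lat = free_lattice(8)
        centre = (4 * 8 + 4) * 8 + 4
        lat.phenotype[centre] = OSTEOBLAST
        rates = CellRates(apoptosis=0.0, differentiation=0.0,
                          proliferation={PROGENITOR: 0.0, FIBROBLAST: 0.0,
                                         CHONDROCYTE: 0.0, OSTEOBLAST: 1.0})
        for day in range(10):
            apply_cell_fates(lat, uniform_class_field(TissueClass.BONE), rates, day)
            lat.check_invariants()
        n = (lat.phenotype == OSTEOBLAST).sum()
        assert 1 < n <= 2**10

    def test_bit_reproducible_day_update(self):
        results = []
        for _ in range(2):
            lat = free_lattice(15)
            rng = np.random.default_rng(3)
            sites = rng.choice(15**3, size=300, replace=False)
            lat.phenotype[sites] = PROGENITOR
            for day in range(3):
                migrate_cells(lat, 36, seed=1000 + day)
                apply_cell_fates(lat, uniform_class_field(TissueClass.BONE),
                                 CellRates(), seed=2000 + day)
            results.append((lat.phenotype.copy(), lat.tissue.copy()))
        assert np.array_equal(results[0][0], results[1][0])
        assert np.array_equal(results[0][1], results[1][1])


class TestTissueRules:
    def test_bone_persists_under_other_stimuli(self):
        lat = free_lattice(4)
        lat.tissue[7] = int(Tissue.BONE)
        lat.phenotype[7] = FIBROBLAST
        deposit_tissue(lat)
        assert lat.tissue[7] == int(Tissue.BONE)

    def test_non_bone_tissue_is_overwritten(self):
        lat = free_lattice(4)
        lat.tissue[7] = int(Tissue.CARTILAGE)
        lat.phenotype[7] = FIBROBLAST
        deposit_tissue(lat)
        assert lat.tissue[7] == int(Tissue.FIBROUS_TISSUE)

    def test_resorption_resets_tissue_to_granulation(self):
        lat = free_lattice(4)
        lat.tissue[:] = int(Tissue.BONE)
        resorb_elements(lat, np.array([int(TissueClass.RESORPTION)], dtype=np.uint8))
        assert (lat.tissue == int(Tissue.GRANULATION)).all()

    def test_granulation_unchanged_by_resorption(self):
        lat = free_lattice(4)
        resorb_elements(lat, np.array([int(TissueClass.RESORPTION)], dtype=np.uint8))
        assert not lat.tissue.any()

    def test_bone_kept_when_element_not_resorbing(self):
        lat = free_lattice(4)
        lat.tissue[:] = int(Tissue.BONE)
        resorb_elements(lat, np.array([int(TissueClass.FIBROUS)], dtype=np.uint8))
        assert (lat.tissue == int(Tissue.BONE)).all()
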