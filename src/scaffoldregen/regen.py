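"""The coupled daily regeneration loop.

One iteration represents one day.  Day 0 is the post-implantation state:
pores filled with granulation tissue, progenitors seeded on the top and
bottom tissue surfaces, one static FE solve, and the initial stimulus
classification (the "initial mechanical signals" screening outcome).
Each subsequent day runs

    cell update (migration -> differentiation -> proliferation/apoptosis,
    driven by the previous solve's stimulus classes)
    -> tissue deposition and elementwise resorption
    -> rule-of-mixtures material update (10-day maturation window)
    -> FE solve -> stimulus classification

for 60 days by default.  The headline outputs are the day-0
bone-favouring volume fraction and the day-60 bone volume fraction, both
relative to the pore (tissue) volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import agents, fe, mechanoreg
from .config import SimulationConfig
from .geometry import ScaffoldDesign, VoxelGrid, voxelize_design
from .mechanoreg import Tissue, TissueClass


@dataclass
class RegenState:
    """Mutable state of one run between daily iterations."""

    day: int
    grid: VoxelGrid
    lattice: agents.AgentLattice
    materials: fe.MaterialField
    composition: np.ndarray        # (ne, 4) site fractions per deposited tissue
    modulus_history: list          # rolling window of (E, nu) snapshots
    classes: np.ndarray | None = None

    def check_invariants(self) -> None:
        self.lattice.check_invariants()
        tis = self.grid.tissue_mask
        s = self.composition[tis].sum(axis=1)
        if not np.allclose(s, 1.0, atol=1e-9):
            raise AssertionError("tissue-element composition does not sum to 1")


def tissue_composition(lattice: agents.AgentLattice, n_elements: int) -> np.ndarray:
    """Per-element fractions of the four deposited tissue types.

    Rows for scaffold elements are zero; rows for tissue elements sum to 1
    (every site of a tissue element is active).
    """
    act = lattice.active
    idx = lattice.site_elem[act].astype(np.int64) * 4 + lattice.tissue[act]
    counts = np.bincount(idx, minlength=n_elements * 4).reshape(n_elements, 4)
    sites_per_elem = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        frac = counts / np.where(sites_per_elem == 0, 1, sites_per_elem)
    return frac


def update_material_field(state: RegenState, config: SimulationConfig) -> fe.MaterialField:
    """Windowed rule-of-mixtures material update.

    Instantaneous element properties are the arithmetic (Voigt) mean of
    the deposited-tissue constants weighted by site fractions; effective
    properties average the last ``window`` instantaneous values (fewer at
    the start of the run) to represent gradual tissue maturation.
    Scaffold elements keep the scaffold constants.
    """
    tp = config.tissues
    E_t = np.array([tp.E[t] for t in range(4)])
    nu_t = np.array([tp.nu[t] for t in range(4)])
    E_inst = state.composition @ E_t
    nu_inst = state.composition @ nu_t
    tis = state.grid.tissue_mask
    E_inst[~tis] = tp.scaffold_E
    nu_inst[~tis] = tp.scaffold_nu
    state.modulus_history.append((E_inst, nu_inst))
    if len(state.modulus_history) > config.window:
        state.modulus_history.pop(0)
    E_eff = np.mean([h[0] for h in state.modulus_history], axis=0)
    nu_eff = np.mean([h[1] for h in state.modulus_history], axis=0)
    return fe.MaterialField(E=E_eff, nu=nu_eff)


def resorb(state: RegenState) -> RegenState:
    """Apply elementwise resorption: deposited tissue in elements whose
    current stimulus class is RESORPTION reverts to granulation."""
    agents.resorb_elements(state.lattice, state.classes)
    return state


@dataclass
class RegenResult:
    design: ScaffoldDesign
    history: pd.DataFrame
    final_state: RegenState
    seed: int

    @property
    def initial_bone_favouring_fraction(self) -> float:
        return float(self.history.loc[0, "favoured_BONE"])

    @property
    def final_bone_fraction(self) -> float:
        return float(self.history["tissue_BONE"].iloc[-1])


def _record(day, classes, lattice, grid) -> dict:
    fav = mechanoreg.favoured_fractions(classes, grid.tissue_mask)
    act = lattice.active
    tfrac = np.bincount(lattice.tissue[act], minlength=4) / act.sum()
    row = {"day": day}
    for c in TissueClass:
        row[f"favoured_{c.name}"] = float(fav[c.name])
    for t in Tissue:
        row[f"tissue_{t.name}"] = float(tfrac[int(t)])
    row["n_cells"] = int((lattice.phenotype[act] > 0).sum())
    row["n_progenitors"] = int((lattice.phenotype[act] == agents.PROGENITOR).sum())
    return row


def run_regeneration(
    design: ScaffoldDesign,
    config: SimulationConfig = SimulationConfig(),
    seed: int = 0,
    check_invariants: bool = False,
) -> RegenResult:
    """Run the coupled FE / agent-based loop for ``config.days`` days."""
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    day_seeds = np.random.default_rng(ss.spawn(1)[0]).integers(
        0, 2**32 - 1, size=(config.days + 1, 2), dtype=np.uint64
    )

    grid = voxelize_design(design, config.element_size)
    lattice = agents.AgentLattice.from_grid(grid, config.sites_per_element)
    agents.seed_initial_cells(lattice, config.seeding_occupancy, rng)
    jumps = agents.jumps_per_day(config.rates.migration_speed, lattice.spacing)
    load = fe.LoadCase(force=config.force, surface=config.load_surface)

    state = RegenState(
        day=0,
        grid=grid,
        lattice=lattice,
        materials=fe.MaterialField(E=np.empty(0), nu=np.empty(0)),
        composition=tissue_composition(lattice, grid.n_elements),
        modulus_history=[],
    )
    state.materials = update_material_field(state, config)

    u, precond = None, None
    rows = []
    for day in range(config.days + 1):
        state.day = day
        if day > 0:
            agents.migrate_cells(lattice, jumps, int(day_seeds[day, 0]))
            agents.apply_cell_fates(
                lattice, state.classes, config.rates, int(day_seeds[day, 1])
            )
            resorb(state)
            state.composition = tissue_composition(lattice, grid.n_elements)
            state.materials = update_material_field(state, config)
        try:
            u, precond = fe.solve_static(
                grid, state.materials, load, x0=u, precond=None, return_precond=True
            )
        except fe.SingularSystemError as err:
            raise RuntimeError(f"FE solve failed on day {day}: {err}") from err
        mech = fe.element_mechanics(u, state.materials, grid)
        state.classes = mechanoreg.classify_field(
            mech.sigma_h, mech.eps_min * 100.0, config.thresholds
        )
        rows.append(_record(day, state.classes, lattice, grid))
        if check_invariants:
            state.check_invariants()

    history = pd.DataFrame(rows).set_index("day", drop=False)
    return RegenResult(design=design, history=history, final_state=state, seed=seed)
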