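# scaffoldregen

Coupled finite-element / agent-based simulation of bone regeneration
inside parametric cubic scaffolds — and the pore-size design study that
compares what a scaffold promises on day 0 with what it delivers after
60 simulated days of healing.

## The problem

Synthetic scaffolds for large bone defects are often designed so that
the mechanical environment *immediately after implantation* favours
bone formation. But regeneration is dynamic: as tissue forms, it
stiffens, the load paths change, and the stimuli that once favoured
bone drift toward fibrocartilage. This package implements an in-silico
framework to quantify that gap for a simple, fully parametric scaffold
family, for researchers in computational mechanobiology and scaffold
design.

The scaffold is a 3 mm cube with three orthogonal families of square
pores (3×3 grids, 1 mm centre spacing). Two parameters define a design:
the horizontal pore size `pore_size_x` (= `pore_size_y`) and the
vertical `pore_size_z`, each 0.1–0.9 mm. Designs with porosity > 50%
are admitted (181 of the 289 on a 0.05 mm grid).

## The model

- **Mechanics.** Voxel FE model (trilinear hexahedra, element size
  h = 0.1 mm nominal): scaffold E = 1000 MPa, ν = 0.3; pores filled
  with granulation tissue E = 0.2 MPa, ν = 0.167 at day 0; bottom face
  encastre; 15 N compression on the top scaffold surface. Solved by
  multigrid-preconditioned CG to a relative residual < 1e-8.
- **Mechanoregulation.** Per element, the stimulus S = (σ_h, ε_min) —
  hydrostatic stress and minimal principal strain — favours exactly one
  outcome: resorption (|ε_min| < 0.01%, |σ_h| < 0.01 MPa), bone
  (|ε_min| ≤ 5%, |σ_h| ≤ 0.15 MPa), cartilage (|ε_min| ≤ 15%,
  σ_h ≤ −0.15 MPa) or fibrous tissue (otherwise).
- **Cells.** A 20 µm agent lattice inside the pores: progenitors seeded
  at 30% occupancy on the top/bottom tissue surfaces migrate at
  30 µm/h, differentiate under the local stimulus into osteoblasts,
  chondrocytes or fibroblasts, which proliferate when matched,
  apoptose when not, and deposit their tissue in place.
- **Coupling.** Daily: cell update → Voigt rule-of-mixtures material
  update (averaged over the last 10 days for maturation) → FE solve →
  new stimulus classes. One iteration = one day; 60 days per design.

Outcomes per design, both relative to the pore volume: the **day-0
bone-favouring volume fraction** (screening proxy) and the **day-60
bone volume fraction** (simulated outcome).

## Worked example

```python
from scaffoldregen import SimulationConfig, make_design, run_regeneration

design = make_design(0.7, 0.8)          # pore sizes in mm
cfg = SimulationConfig(element_size=0.15)   # reduced study profile
res = run_regeneration(design, cfg, seed=0)
print(f"initial bone-favouring {res.initial_bone_favouring_fraction:.1%}, "
      f"day-60 bone {res.final_bone_fraction:.1%}")
```

prints

```
initial bone-favouring 91.9%, day-60 bone 49.0%
```

i.e. for this design 91.9% of the pore tissue sees bone-favouring
mechanical signals right after implantation, and the coupled simulation
deposits bone in 49.0% of the pore volume by day 60.
`res.history` holds the full per-day time series (favoured-class
fractions, deposited-tissue fractions, cell counts) as a DataFrame.

The same from the shell:

```
$ scaffoldregen enumerate --out designs.csv
289 candidates, 181 admitted -> designs.csv
$ scaffoldregen simulate --psx 0.7 --psz 0.8 --element-size 0.15 --seed 0
$ scaffoldregen screen-initial          # day-0 sweep of all 181 designs
$ scaffoldregen sweep --days 60         # the full study (long)
```

The headline of the study reproduces in miniature: design (0.6, 0.1)
screens at ~99% bone-favouring signals on day 0 yet regenerates only
~14% bone by day 60 — its 0.1 mm vertical pores throttle cell
infiltration — so day-0 mechanical screening is not a proxy for
regeneration outcome.

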