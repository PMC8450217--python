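# Methods

`scaffoldregen` simulates bone regeneration inside a parametric cubic
scaffold by coupling a voxel finite-element (FE) model of the
scaffold–tissue construct to a lattice agent-based model (ABM) of the
cell populations in the pores, and sweeps the two pore-size parameters
to compare day-0 mechanical screening with the simulated 60-day outcome.
This note records the model, its tunables, and the numerical and design
choices; the README shows how to run it.

## Geometry and design space

The scaffold is a cube of side 3 mm pierced by three orthogonal families
of square pores: nine per axis on a regular 3×3 grid with 1 mm centre
spacing. Pore centres sit at 0.5/1.5/2.5 mm in each transverse axis —
the only placement of a 1 mm-spaced 3×3 grid that keeps a 0.9 mm pore
inside the cube. Pores along x and y share one edge length
(`pore_size_x`); pores along z have an independent one (`pore_size_z`);
both range over 0.1–0.9 mm. The union of the 27 prisms is the
regenerating-tissue region; its volume fraction of the cube is the
porosity.

Membership in the pore union uses half-open intervals
[centre − s/2, centre + s/2) so that voxel counts never depend on
floating-point ties. Porosity is computed by voxel counting at 0.025 mm
resolution; because every pore boundary of the 0.05 mm-step design grid
falls on a line of that grid, the voxel count equals the exact
inclusion–exclusion volume for all 289 candidate designs (the test suite
asserts this against the closed form). The design sweep samples both
pore sizes at 0.05 mm steps (17 × 17 = 289 candidates) and admits
designs with porosity strictly above 50%, which yields 181 designs; the
(0.5, 0.5) design sits exactly at 50% and is excluded by strictness.

## Finite-element model

The cube is discretized into an n³ grid of cubic 8-node trilinear
hexahedra; each element is scaffold or tissue according to whether its
centroid lies in the pore union. A conforming shared-node mesh bonds
tissue to scaffold (the tie constraint comes for free). Materials are
isotropic linear elastic, one material per element:

| phase              | E (MPa) | ν     |
|--------------------|---------|-------|
| scaffold           | 1000    | 0.3   |
| granulation tissue | 0.2     | 0.167 |
| fibrous tissue     | 2       | 0.167 |
| cartilage          | 10      | 0.167 |
| bone               | 1000    | 0.3   |

Scaffold and granulation values anchor the model; the fibrous,
cartilage and bone moduli follow the fracture-healing model lineage this
simulator derives from and are exposed in the configuration as
calibration parameters.

Boundary conditions: the bottom face is fully fixed ("encastre"); a
total compressive force of 15 N is applied as a uniform traction on the
top face. By default the traction covers only the scaffold-material
facets of the top face (`load_surface="scaffold"`); distributing it over
the whole face, including the soft tissue facets, is available as
`load_surface="full"`. The scaffold-only default was fixed by a single
calibration pass against the day-0 screening values of the two reference
designs: scaffold-only loading reproduces the ~99%/~98% bone-favouring
fractions of designs (0.5, 0.9) and (0.6, 0.1), whereas a uniform
full-face traction drives the soft top-surface tissue of large-pore
designs into the high-strain regime and collapses their day-0 bone
fraction to ~30%, which is inconsistent with the screening outcomes the
model must reproduce. Physically, the scaffold-only option approximates
load introduction through a stiff plate that bears on the scaffold
struts.

Element stiffness splits as K_e = λ K_λ + μ K_μ with two geometry-only
24×24 matrices integrated by 2×2×2 Gauss quadrature, so global assembly
over a heterogeneous material field is a vectorized linear combination;
the COO→CSR scatter pattern is cached per mesh. Strains are evaluated
once per element at the centroid (single-point evaluation of the
trilinear gradient), matching the element-wise granularity of the
stimulus; stresses follow from Hooke's law, the hydrostatic stress is
tr(σ)/3 (compression negative) and the minimal principal strain is the
smallest eigenvalue of the strain tensor.

The linear systems (up to ~90 000 dof at 0.1 mm) are solved by conjugate
gradients preconditioned with a geometric multigrid V-cycle: voxel
hierarchies coarsened by factors of 2 or 3, Galerkin coarse operators
(RAP with trilinear interpolation), Chebyshev–Jacobi smoothing (3 steps,
spectral bound from 10 power iterations), and a direct factorization on
the coarsest level. Convergence is required to a relative residual below
1e-8 so that the downstream stimulus classification is deterministic;
systems under 10 000 dof go straight to a sparse LU. Daily solves in the
coupled loop warm-start from the previous day's displacement field. The
5000:1 stiffness contrast between scaffold and granulation tissue keeps
the preconditioned iteration count near 80 at 0.1 mm resolution.

## Mechanoregulation

Each tissue element's stimulus (σ_h, ε_min) maps to exactly one favoured
class by an ordered rule list (first match wins; strains in percent,
stresses in MPa):

1. resorption: |ε_min| < 0.01 and |σ_h| < 0.01
2. bone: |ε_min| ≤ 5 and |σ_h| ≤ 0.15
3. cartilage: |ε_min| ≤ 15 and σ_h ≤ −0.15
4. fibrous tissue: otherwise

The bone and cartilage bounds are the classical tissue-differentiation
thresholds (intramembranous ossification at low distortion and low
hydrostatic stress; the endochondral route under compressive
hydrostatic stress); the cartilage rule requires compression, so hydrostatic tension
at moderate strain classifies as fibrous. The resorption bounds have no
published values; the defaults sit well below the model's operating
strain range (day-0 tissue strains concentrate around 0.5–2%), making
the resorption zone reachable but rare. All five bounds are
configuration parameters.

## Agent-based model

Cells occupy a cubic site lattice with 5×5×5 sites per FE element
(20 µm spacing at the nominal 0.1 mm resolution — one site per cell).
Sites are active where the containing element is tissue; at most one
cell per site. Each cell is a progenitor, fibroblast, chondrocyte or
osteoblast; each site also carries one deposited tissue (granulation at
day 0). Day 0 seeds progenitors on a uniformly random 30% of the active
sites in the top and bottom lattice layers (bone-marrow-like sources);
the interior starts cell-free.

Per day, in this order:

1. **Migration** — progenitors only, at 30 µm/h: jumps_per_day =
   round(30·24/spacing_µm) attempted single-site moves to a uniformly
   random 6-neighbour, rejected at occupied, inactive or out-of-lattice
   targets; the cell order is reshuffled every sweep.
2. **Differentiation** — a progenitor whose element favours bone,
   cartilage or fibrous tissue becomes the matched phenotype
   (osteoblast/chondrocyte/fibroblast) with probability 0.3/day.
3. **Proliferation / apoptosis** — in random order: progenitors and the
   stimulus-matched phenotype divide with their daily probability
   (progenitor 0.60, fibroblast 0.55, chondrocyte 0.20, osteoblast
   0.30), placing the daughter in a uniformly random empty active
   neighbour (skipped if none); differentiated phenotypes that mismatch
   the stimulus apoptose at 0.05/day; under a resorption stimulus every
   cell apoptoses at that rate. Progenitors are treated as precursors:
   they differentiate rather than apoptose under differentiated-tissue
   stimuli, and newly differentiated cells may divide the same day.
   Daughters act from the next day.
4. **Deposition** — every differentiated cell overwrites its site's
   tissue with its product, except that deposited bone is never
   overwritten; elementwise resorption (below) is the only pathway that
   removes bone.
5. **Resorption** — sites of elements currently classified resorption
   revert to granulation. Cells are not removed here beyond the
   apoptosis rule; tissue and cell bookkeeping stay orthogonal.

All stochastic kernels are numba-compiled and draw from explicit
per-day seeds derived from the run seed, so a run is bit-reproducible.

## Coupling and the daily loop

After the cell update, each tissue element's instantaneous properties
are the arithmetic (Voigt) rule-of-mixtures average of the deposited
tissue constants weighted by site fractions; the effective properties
are the mean of the last 10 instantaneous values (shorter at the start
of the run; no padding), representing gradual tissue maturation. A fresh
FE solve with the updated field then produces the next day's stimulus
classes. Day 0 is evaluated on the all-granulation state before any
cell activity — this is the "initial mechanical signals" screening
outcome. One iteration is one day; runs last 60 days.

Outcome metrics, both relative to the pore (tissue) volume: the day-0
bone-favouring volume fraction (fraction of tissue elements in the bone
zone) and the day-60 bone volume fraction (fraction of active lattice
sites carrying bone).

## Study driver

The sweep enumerates the 17×17 grid, filters porosity > 50%, and runs
day-0 screening and/or the full simulation per design. Per-design RNG
streams derive from (master seed, pore sizes, replicate), so results are
independent of sweep order and subsets. The sweep CSV is written
incrementally and keyed by configuration hash; restarts skip completed
designs and reproduce an uninterrupted run exactly. One replicate per
design is the default, mirroring the study; the Spearman correlation
between day-0 and day-60 outcomes quantifies the headline discrepancy.

## Problem sizes and the reduced study profile

The nominal configuration (0.1 mm elements → 30³ grid; 20 µm lattice →
150³ sites) is the package default and is used for all day-0 quantities
(single static solves). For the 60-day coupled runs the package's study
profile uses 0.15 mm elements with a 30 µm lattice (20³ elements, 100³
sites, 24 migration jumps/day): a full 60-day run then takes tens of
seconds on one CPU instead of several minutes, which is what makes the
multi-seed reference runs and the sub-grid sweep in the test suite and
acceptance script practical. 0.15 mm is the coarsest element size that
resolves every design: the 0.1 mm scaffold walls between 0.9 mm pores
vanish at 0.2 mm. The solver's accuracy contract — asserted in the test
suite — is that the day-0 bone-favouring fraction of design (0.5, 0.9)
moves by less than 2 percentage points between 0.15 mm and 0.1 mm
elements. Two caveats of the coarser profile are measured and documented
rather than hidden: 0.1 mm pores widen to one 0.15 mm element, easing
cell infiltration slightly, and knife-edge day-0 classifications shift
(the >98% screening count is 106 at 0.1 mm but 80 at 0.15 mm, which is
why screening always runs at 0.1 mm).

## What the generator emulates, and limits of interpretation

All inputs are synthetic by construction: the geometry module *is* the
study's input generator, and the cell model is initialized from the
stated seeding protocol. The simulation emulates mechanically regulated
tissue differentiation in an idealized construct; it does not model
curved or anatomical geometries, bending or torsion, scaffold
degradation, surface-guided (curvature) growth, nutrient or oxygen
transport, or nonlinear/anisotropic tissue behaviour. Passing tests
therefore show that the implementation reproduces the model's
behaviour under its own assumptions, not that the model predicts any
particular in vivo outcome.

Where published values end, lineage defaults begin: the cell rates, the
non-granulation tissue moduli and the resorption bounds are defaults
from the cited model family, not fitted quantities. Two observed
consequences, measured at the study profile with three seeds: the
model reproduces the reference outcomes for the best design
(~49% vs ~44%) and the infiltration-limited design (~14% vs ~16%), but
over-predicts design (0.5, 0.9) (~58% vs ~40%), so the fine ranking
between the two best designs inverts; and because the resorption zone
is nearly unreachable, 76 stiff small-pore designs saturate at exactly
100% day-0 bone-favouring signals, making the day-0 argmax a tie rather
than uniquely (0.5, 0.9) (which sits at 99.8%). Both are plausibly
controlled by the unpublished resorption-zone extent and exact cell
rates of the original implementation; the configuration exposes every
such parameter.

## Numerical conventions worth knowing

- 3-D arrays are indexed (ix, iy, iz), flattened C-order; node
  (ix·(n+1)+iy)·(n+1)+iz; dof 3·node+component.
- Compression is negative throughout; classifier strains are percent.
- Voxel labelling uses element centroids; no partial-volume elements.
  Porosity is always reported from the fine 0.025 mm grid, decoupled
  from the FE resolution.
- Boundary ties in pore membership resolve by the half-open convention;
  classifier boundary ties resolve by rule order (first match wins).
- The agent lattice spacing is element_size/sites_per_element; the
  jumps-per-day count rounds 720 µm of daily path length to whole site
  hops.
- Degenerate inputs fail loudly: out-of-range pore sizes, non-divisor
  element sizes, designs whose voxelization loses all scaffold or all
  tissue, empty load surfaces, and unconverged solves all raise with a
  message naming the offender.
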