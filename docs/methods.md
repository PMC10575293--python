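# Methods

`ossify` simulates bone regeneration inside 3D-printed scaffolds implanted in
a critical-size long-bone defect by coupling two models on one shared voxel
grid: a linear-elastic finite-element (FE) model that computes the local
mechanical environment, and a lattice agent-based model (ABM) of mesenchymal
stem cell (MSC) activity that turns that environment into tissue. This note
records the model, its assumptions, the parameter choices, and the numerical
and design decisions that were genuinely open.

## Anatomy and geometry

The simulated anatomy is a rat femoral segmental defect: two intact cortical
bone segments (tubes of 0.5 mm wall around 2 mm-diameter marrow, 3 mm long
each) separated by a 5 mm gap, a callus cylinder 9 mm long and 5 mm in
diameter overlapping the cortical ends, a facial fixation plate (9 x 2 mm,
PEEK) with four 0.5 x 3.5 mm screws, and a scaffold centered in the gap.
Everything is rasterized at a 0.05 mm pitch (voxel centers at
(i + 1/2) h; bone axis = z). The callus is generated first and the other
phases are carved out of or laid over it in priority order, so scaffold pores
remain callus phase and belong to the healing region — the Boolean
construction mirrors how the callus envelope is defined around the implant.

The callus outer shape is described in the source anatomy only pictorially
(an "arc" around the defect). We realize it as a full cylinder; the resulting
annulus around the intact bone ends supplies the periosteal surface. The
periosteal MSC source is the one-voxel callus shell adjacent to the outer
cortical surface; the marrow MSC source is the one-voxel marrow disk at each
cut bone face. Both choices are geometric stand-ins for biological membranes
the voxel model cannot resolve.

Scaffolds are orthogonal filament lattices: layers of parallel rectangular
filaments stacked along z, alternating orientation between x and y, with
longitudinal pore gaps between layers. Layer orientation is indexed from the
nearest scaffold end, and layer membership of a voxel uses a majority-overlap
rule, so every design's rasterization is mirror-symmetric about the defect
mid-plane. The four designs:

* **VALIDATION** — 3 mm diameter x 3 mm long, 0.4 mm filaments, 0.8 mm
  pores (the HA-PELGA implant of the in vivo reference study). 0.4/0.8 does
  not tile 3 mm (2.5 periods), so the layout is three filaments with two
  interior 0.8 mm pores and 0.1 mm end clearances absorbed into edge pores.
* **REG / IREG1 / IREG2** — 3 mm diameter, spanning the full 5 mm defect
  (the source only fixes pore/filament sizes; spanning the gap makes
  "edge-to-center" gradients meaningful; the length is configurable). Radial
  filament 0.2 mm, radial pore 0.25 mm. Longitudinally: five filament/pore
  pairs per half, mirrored about the mid-plane — uniform 0.2/0.3 mm (REG), or
  equal filament and pore sizes graded linearly in [0.1, 0.4] mm, increasing
  towards the center (IREG1) or decreasing (IREG2).

A **miniature** variant (1.5 mm defect, 2 mm callus, no fixation plate) is a
0.5x scale model of the case-study designs preserving their relative
geometry — REG style 0.1/0.15 mm uniform (40% longitudinal fill), IREG styles
graded 0.05–0.2 mm with the full 4:1 edge-to-center contrast (50% fill). It
exists so that replicate studies of the gradient effect run in seconds; its
loads (3.7 N compression, 1.2 N shear) scale the full model's loads by the
ratio of cortical cross-section areas, preserving nominal bone stress.

## Mechanics

Standard 8-node trilinear hexahedra with 2x2x2 Gauss quadrature, one element
per k^3-voxel block (default k = 4, i.e. 0.2 mm elements, with the stimulus
broadcast to member voxels; k is configurable and the validation runs in this
package use finer/coarser settings as stated below). Because all elements
are congruent cubes, the element stiffness is h (lambda K_lambda + mu K_mu)
with two precomputed geometry matrices, making assembly a vectorized scatter.
Element Lame constants are block means of voxel values; voxels outside the
domain contribute zero stiffness (boundary softening). Plate/screw/bone
connections arise implicitly from shared nodes on the common grid.

Materials (MPa, Poisson): granulation 0.2/0.167, fibrous 2/0.167, cartilage
10/0.3, cortical bone 8000/0.3, marrow 2/0.167, HA-PELGA 350/0.3, PEEK
3800/0.36, case-study scaffold 1000/0.3. Newly formed (woven) bone is not
intact cortical bone; its modulus defaults to 1000 MPa (configurable), with
8000 MPa reserved for the intact cortex.

Boundary conditions: the proximal end face (cortical + marrow) is fully
constrained. The 17.7 N axial compression is applied on the distal cortical
face and the 5.7 N shear transversely on the distal end face, each spread
uniformly over the face nodes. (The source text places the compression on
the proximal side while also fully constraining it; a load on fixed nodes
does nothing, so the mechanically meaningful distal application is used. The
shear's true application area — the femoral mid-shaft — is likewise
unprinted; the distal end face is the stated approximation.)

The constrained system is solved by Jacobi-preconditioned conjugate
gradients to a true relative residual of 1e-8 (1e-13 in desk tests),
warm-started from the previous solve during coupled runs. Assembly refuses
disconnected load-bearing regions (they would make the constrained operator
singular). Per element, the centroid small-strain tensor yields gamma (the
algebraically smallest eigenvalue, compression negative) and the hydrostatic
stress p = -tr(sigma)/3 (compression positive).

## Mechanoregulation

The stimulus is S = |gamma|/a + |p|/b with a = 0.0375 and b = 0.003.
Magnitudes are used because the underlying stimulus theory is defined on
them; signed inputs would make S sign-ambiguous. The constant b is printed
in its source with units of mm/s — it descends from a poroelastic
fluid-velocity stimulus — while p here is a stress. No principled rescaling
exists, so b is applied literally to p in MPa; this is a documented
convention, not a unit conversion, and both constants are configurable.

S maps to outcomes: S < 0.011 → resorption of formed bone; S ≤ 1 → bone;
S ≤ 3 → cartilage; else fibrous tissue. The interval breakpoints are the
defaults of the mechanoregulation literature this rule family comes from
(the source model cites but does not print its own); they are fully
configurable, and boundary values belong to the lower interval. Resorption
removes only formed bone (reverting it to granulation), never scaffold
material.

## Cell lattice

At most one cell per 50 um site; tissue labels live on the same sites. Daily
kinetics (events/cell/day), with baseline rates during the 7-day latency
period and reduced rates from day 8:

| cell        | proliferation (base/after) | apoptosis | differentiation (base/after) |
|-------------|---------------------------|-----------|------------------------------|
| MSC         | 0.3 / 0.12                | 0.05      | 0.3 / 0.06                   |
| fibroblast  | 0.275 / 0.11              | 0.05      | —                            |
| chondrocyte | 0.1 / 0.04                | 0.1       | —                            |
| osteoblast  | 0.15 / 0.06               | 0.16      | —                            |

MSC migration is 7 uniform face-neighbor jumps per day; a jump succeeds only
into an empty healing site. The nominal migration speed of 30 um/h
(720 um/day) conflicts with 7 x 50 um = 350 um/day; the jump count is
implemented literally and exposed in the configuration. Initial conditions:
the healing region is filled with granulation tissue and exactly
round(0.3 N) MSCs are sampled without replacement from the periosteal +
marrow source masks (exact-count seeding keeps small-mask runs
reproducible).

The daily sub-step order is migrate → proliferate → differentiate → deposit
→ apoptose. The source does not fix an order; since order affects results it
is fixed here and not configurable. Differentiating MSCs adopt the phenotype
of their site's stimulus class (bone → osteoblast, cartilage → chondrocyte,
fibrous → fibroblast; resorption flags the site and leaves the MSC);
phenotypes never revert. Deposition writes each differentiated cell's tissue
under it and applies pending resorption flags. Stochastic sub-steps are
synchronous vectorized rounds: all eligible cells draw events from one
shared generator and conflicting claims on a target site are resolved by a
fresh random priority permutation, losers forfeiting. Within one round a
cell cannot enter a site vacated in that same round — a deliberate,
documented difference from a strictly sequential sweep that removes
directional artifacts and keeps the per-cell event statistics exact.

## Coupling and schedule

One iteration = one healing day; the default horizon is 112 days (16 weeks).
The FE problem is solved before day 1 so the latency-period differentiation
has a stimulus, and re-solved after every material update. Updates happen
every 3 days — and once more at the final day if it is not an update day —
using the mean of the last three days' element stimuli; the material of each
healing voxel is set from its tissue label and the FE block mean realizes
the volume-weighted mixture per element. Between solves the ABM reuses the
last solved field each day. A run therefore performs
ceil(total_days/3) + 1 FE solves. Full state (lattice, materials, stimulus
history, RNG state) is checkpointable; stopping at any day and resuming
reproduces the uninterrupted run bit-exactly.

## Outputs

Per-day snapshot CSVs (x/y/z index, cell code, tissue code; osteoblast
fixed at code 2) and tissue-volume series (site count x h^3, exactly).
Weekly reporting samples days 28/56/84/112. The packaged validation
reference holds the in vivo bone volumes 3.7 ± 1.5 mm^3 (4 weeks) and
22.5 ± 3.8 mm^3 (16 weeks) with the simulation values reported alongside
them (5.1 and 18.9 mm^3); a model value passes when it lies within the SEM
band. The 8- and 12-week reference values appear in the source only as a
figure and are not packaged. For the gradient case study, "bone over the
healing period" is the sum of the four weekly volumes (the source is
ambiguous between final and cumulative; this is configurable in analysis).

## Problem sizes used by the test suite and acceptance script

The full-size validation domain at 0.05 mm pitch has ~1.1 million healing
sites and FE systems of ~10^5–10^6 unknowns; a 112-day run at that size is
an hours-long computation. The packaged studies therefore run at reduced
scale, chosen as the package's own standard configurations: the validation
run uses a 0.1 mm lattice (k = 3 FE coarsening, ~138,000 healing sites,
112 days, ~3 minutes), and the gradient case study uses the miniature domain
(~48,000 healing sites, 28 days, 10 replicates per design). At these sizes
the simulator reproduces the qualitative validation behavior (early bone
formation at the periosteal/marrow sources, fibrous tissue in the
high-stimulus gap) and the directional case-study result (the IREG2-style
gradient forms more bone than the uniform design in a majority of
replicates). Quantitative agreement with the full-scale printed volumes is
not expected at reduced resolution: the site volume is 8x larger, the cell
population correspondingly smaller, and the stimulus field coarser.

## What the synthetic conditions do and do not show

All inputs are generated internally from the printed geometry, material,
kinetic and loading tables; there is no external data. The model omits — by
design, matching its source — scaffold degradation, revascularization,
nutrient and oxygen transport, callus shape evolution, endochondral
transdifferentiation, cell mechanics, and any statistical variation of the
kinetic rates themselves (all stochasticity is in event sampling). Passing
tests therefore demonstrate internal correctness (mechanics against analytic
and oracle solutions, event statistics against the kinetic table,
bit-reproducibility) and the mechanobiological direction of the pore-gradient
effect, not a calibrated prediction of in vivo healing.

## Known limitations

* Linear elasticity with small strains, while soft granulation tissue under
  the applied loads reaches strain magnitudes far beyond the small-strain
  regime; the stimulus rule inherits this (as does its source model).
* The b-constant unit mismatch above.
* Voxel stair-casing of curved surfaces; tie constraints only through shared
  nodes.
* Bone volume can plateau or decline at reduced scale when stiffened tissue
  shields interior regions below the resorption threshold; the resorption
  breakpoint is the least constrained parameter in the rule set.
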