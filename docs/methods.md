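# Methods

## Scope and model

`stemfea` evaluates tibial extension stems for total knee arthroplasty by
linear-elastic finite-element analysis of a bone-implant assembly under
physiological compressive loads. Six implant configurations are compared on
one tibia: a cementless baseplate alone (model 1) and the same baseplate
with press-fit extension stems of 20/45/70 mm length and 9/12.5/14 mm
diameter (models 2-6). The comparison targets two antagonistic effects of a
stem: *stress shielding* (unloading of the bone directly beneath the
baseplate) and *distal load concentration* (elevated compressive strain in
the bone surrounding the stem, strongest at its tip).

Assumptions, in decreasing order of importance:

- **Small-strain linear elasticity.** Bone and implant are isotropic linear
  elastic; all outputs scale linearly with load. Consequently only one
  factorization per model is needed — the three load cases (3/5/12 x body
  weight) are obtained by scaling, which is exact. A config flag
  (`independent_solves`) forces separate solves as an audit.
- **Bonded (osseointegrated) interface.** The implant and bone displace
  together at their interface — secondary, post-osseointegration stability.
  Primary stability, friction and micromotion are out of scope.
- **Compression only.** The joint load acts along the mechanical axis
  defined at the resection; no shear, torque or varus/valgus moments.

## Synthetic tibia phantom

No patient imaging ships with the package; a parametric phantom stands in
for the proximal tibia, built so that its apparent-density field is known in
closed form everywhere (the rasterizer writes HU as the exact inverse of the
density calibration, plus optional truncated Gaussian noise). Geometry is a
loft of superellipse cross-sections along the shaft axis: a circular
diaphysis (default radius 11 mm) flaring quadratically from 60% of the
length into a boxy 72 x 48 mm plateau, 120 mm of bone in total.

The density field has four anatomical features, all config-exposed:

| feature | default | rationale |
|---|---|---|
| cortical shell | 1.85 g/cm^3; 4.5 mm thick distally thinning to 1.5 mm proximally | diaphyseal cortex is thick, metaphyseal cortex thin |
| cancellous gradient | 0.30 g/cm^3 at the axis to 0.60 at the endosteal edge | trabecular density rises toward the cortex |
| medullary canal | marrow at 0.15 g/cm^3 over ~55% of the endosteal radius in the diaphysis, fading through the flare | the diaphysis is a marrow-filled tube, not a trabecular continuum |
| subchondral densification | cancellous density x2.0 over the last 15 mm below the plateau | the resection exposes dense epiphyseal bone, which is what a baseplate actually rests on |

The last two features matter mechanically: without the subchondral band the
no-stem baseplate presses on implausibly soft bone and its under-plate
strains dominate every percentile; without the canal the stem tip is
artificially well supported. With them, the phantom reproduces the
qualitative load-transfer contrast reported for the real tibia.

What the phantom does **not** emulate: trabecular microarchitecture,
anisotropy, cortical porosity, anatomical asymmetry (it is mirror-symmetric
up to the oblique resection), the fibula, and scanner artifacts other than
additive Gaussian noise. Passing tests on the phantom therefore validate
the *pipeline* (geometry, integration, mechanics, statistics), and the
*direction* of the stem comparisons — not patient-specific magnitudes.

## HU -> density -> modulus

Density calibration is linear, `rho = a*HU + b`, defaulting to
`a = 0.001 g/cm^3 per HU, b = 1.0` (water ~1.0 g/cm^3, dense cortical
~1.8-2.0). QCT calibrations are scanner-specific and no fidelity claim is
made for the default; the phantom always uses the configured calibration, so
every test is calibration-independent.

Per-element density is the 4-point Gauss average of the trilinearly
interpolated CT field over each tetrahedron (exact for affine density
fields; verified against dense Monte-Carlo integration on smooth fields).
Moduli follow two power laws (E in MPa, rho in g/cm^3):

    E_cortical   = 3890 * rho^2.39
    E_cancellous = 6570 * rho^1.37      nu = 0.3 for both

classified by the density at which the laws intersect,
`rho* = (6570/3890)^(1/1.02) = 1.6715 g/cm^3` (conventionally quoted
rounded as 1.68). The intersection is the default threshold so that
"classify by threshold" and "classify by whichever law gives the larger
modulus" agree exactly; an explicit threshold can be configured. Floors of
0.05 g/cm^3 and 10 MPa guard against air/marrow voxels caught in the mesh;
applications of the floor are logged. The implant (baseplate and stem) is
cobalt-chrome-molybdenum: E = 220 GPa, nu = 0.3. Modulus is constant per
element (not per quadrature point), matching the element-integration
description of the mapping procedure.

## Geometry and virtual surgery

Solids are implicit (approximate signed-distance functions); booleans are
min/max compositions, so resection and cavity carving cannot produce
non-manifold geometry, and watertight surfaces are extracted by marching
cubes only for I/O and audits. The resection removes the bone 2 mm below
the proximal apex on a plane tilted 3 degrees (joint-line obliquity) about
the antero-posterior axis. The implant is a parametric stand-in for a
commercial cementless component: a rounded-rectangular baseplate (4 mm
thick) sized to 85% of the resection-face spans (maximal coverage without
protrusion, checked explicitly), four radial fins at the stem root, and a
bullet-nosed cylindrical stem (hemispherical tip). The implant frame is
rotated to the resection normal, so the plate rests flush on the cut and
the load axis equals the cut normal; the stem consequently tilts 3 degrees
from the anatomical shaft axis, which keeps the plate fully supported —
the alternative (stem along the shaft axis) leaves a wedge-shaped gap under
half the plate.

## Meshing

One Delaunay tessellation covers bone and implant together; elements are
classified by which solid contains their centroid, so the two bodies share
interface nodes and the bonded contact needs no constraint equations. Seed
points are boundary-surface samples plus jittered interior lattices: global
spacing (default 1 mm at full scale; the desk-scale preset uses 4 mm) away
from the implant, contact spacing (0.75 x global) within a 3 mm offset of
the interface — the refined region of interest (ROI) over which strain
percentiles are later computed. Slivers below a scaled shape quality of
0.05 are discarded; interior nodes are then improved by damped Laplacian
smoothing that never moves a boundary sample, never leaves the domain, and
reverts any move that would push an element below the quality floor.
Midside nodes sit at edge midpoints: elements are straight-sided TET10 with
constant Jacobians, so a 4-point Gauss rule integrates stiffness exactly.
Meshing is deterministic (fixed internal jitter stream): identical inputs
give identical meshes.

## Boundary conditions and solve

All nodes within 1 mm of the distal cut plane are fully fixed. The joint
load is applied as uniform pressure on the superior baseplate face, split
into a medial patch carrying 60% of the force and a lateral patch carrying
40% (patches are the plate-top boundary faces on either side of the
sagittal midplane; faces straddling the midplane carry no load so the split
is exact). Consistent nodal loads of the quadratic face functions are used
— for a straight 6-node triangle under uniform traction each midside node
carries one third of the face load and corners none. Load cases: walking
3 x BW = 2250 N, stairs/sit-to-stand 5 x BW = 3750 N, running
12 x BW = 9000 N, at 750 N body weight. The system is solved by sparse LU
after eliminating constrained dofs; the relative residual must be below
1e-8 and the reactions are checked against the applied loads.

## Outputs

Element strain is the volume-averaged (= centroid, for straight elements)
symmetric displacement gradient; stress follows by Hooke's law. Reported
per (model, load case), maxima over *bone* elements only:

- **von Mises stress** (MPa);
- **equivalent elastic strain**: the von-Mises invariant of the strain
  deviator with the common FE-package factor 1/(1+nu), so that in uniaxial
  stress it equals sigma_vM/E exactly (the stress-based form sigma_vM/E is
  available as an alternative convention);
- **fracture risk** RF = 100 x |principal strain|_max / 0.00728, where the
  ultimate strain is 70% of the compressive yield strain of bone (0.0104).
  The magnitude of the extreme principal strain is used: the limit derives
  from compression and the loading is compressive, so tensile and
  compressive peaks are treated symmetrically (a signed variant is
  available);
- **ROI micro-strain percentiles**: median and 90th percentile of the
  magnitude of the minimum (most compressive) principal strain over bone
  elements of the refined interface zone, reported in micro-strain with the
  compressive sign, using the linear-interpolation percentile estimator so
  results are deterministic.

Maxima are taken over element-averaged values, not nodal extrapolations, to
avoid recovery-artifact spikes.

## Mesh-refinement protocol and a known limitation

The convergence protocol reruns a configuration at descending element sizes
and accepts the first size at which every monitored output (the three
bone-field maxima) changes by less than 5% relative to the previous size;
if none does, the finest size is reported with `converged=False` — the
protocol never claims convergence it did not observe.

At the desk-scale sizes this package runs by default (a 7 -> 5.6 -> 4.5 ->
3.6 mm ladder on the default phantom, chosen to fit a single-CPU,
minutes-long budget), the *global* response converges quickly — the load
compliance changes by well under 5% between the two finest sizes — but the
pointwise field maxima do not reliably meet the 5% band: the extreme value
over ~20-70k unstructured elements is carried by a single element near a
strain concentration (the stem tip indenting soft metaphyseal bone) and
fluctuates by ~10% between independent tessellations. Stabilizing such
extrema is exactly why the original protocol refined to 0.75-1 mm elements
(~2.6 million per model), a resolution outside a desk-scale budget. The
limitation is documented rather than hidden: percentile-based ROI
statistics (median, p90), which drive the stem comparisons, are stable
across refinement; single-element maxima at coarse resolution should be
read with that caveat.

## Problem sizes used by the shipped tests

The test suite and the acceptance script run entirely on synthetic inputs:
a reduced phantom (60 mm shaft) for unit tests, and the default phantom at
the `--coarse` preset (4 mm global / 3 mm contact elements, ~1 mm CT
voxels, ~20-35k nodes per model) for the six-model study, which completes
in minutes on one CPU. Full-scale settings (1 mm / 0.75 mm) are the
package defaults for production use and scale the same pipeline unchanged.
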