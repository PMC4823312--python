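# Methods

This note documents the models, numerical choices and known limitations of
`megfem`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synthetic head phantom

The phantom stands in for a small-animal head whose anatomy is not
available: it reproduces the *topology* of such a model — nested
compartments, a three-layer skull, conducting defects, a thin conducting
film on the surface — not any particular anatomy.

A `LabeledVoxelGrid` holds integer tissue labels on a regular isotropic
grid (0-based indices; world coordinates in mm at voxel centers;
right-handed axes with +z toward the sensor array). Two shapes are
generated: a sphere (for analytic validation — the closed-form sphere
field and potential apply) and a mildly anisotropic ellipsoid with axis
scales (1.15, 1.00, 0.95) used by the bundled study. Shells, outside in:
scalp/body, compact bone, cancellous bone, compact bone, gray matter,
white matter. Optional labels (CSF, vessels, ocular media) exist in the
conductivity table but are not placed by the default generator, matching a
model in which no CSF film around the brain is differentiated. After shell
assignment, any cancellous voxel with a face neighbor outside the skull is
relabeled compact, so the spongy layer is enclosed by compact bone at any
grid resolution. The liquid film is the 1-voxel face-neighborhood dilation
of the head into the background; the operation is idempotent.

Conductivities (S/m): scalp 0.33, compact bone 0.004, cancellous bone
0.046, gray matter 0.23, white matter 0.31 (isotropic equivalent), CSF
1.79, vessels 0.78, ocular humor 1.7, lens 0.35, agar defect filling 1.0,
liquid film 0.6. All are configurable per study.

Skull defects are cylinders: every bone voxel within `radius` of the axis
through the defect center (outward surface normal) is relabeled to the
fill label; nothing else changes. The default radius is 2.5 mm — the
physical defect diameters are not published, and 5 mm lets two defects and
the source line coexist on a ~3 cm head. Defect 2 of the default study is
laterally offset 2 mm from the shift line: in a perfectly mirror-symmetric
arrangement the reorientation of sources next to the defects is
structurally forbidden (symmetric spherical models famously show no
orientation errors), so the generator keeps the asymmetry that a physical
experiment inevitably has.

Sources sit on a `ShiftLine` tangential to the inner skull, 1.5 mm below
it, stepped in half-steps of 0.3455 mm so that a full step is exactly the
0.691 mm screw advance of the physical fixture; the default moment is
130 µAmm along the line. *Shift eccentricity* is 0 at the normal
projection of the defect center onto the line and ±1 at the projections of
the outermost defect-edge points; sources with |e| ≤ 0.5 form the
"under-defect" group and |e| ≥ 1.3 (configurable) the "next-to-defect"
group.

The sensor model is a 4×4 planar array of axial first-order gradiometers:
bottom coils coplanar (6 mm pitch, 3 mm above the head surface by
default), axes along +z, signal = bottom-coil minus top-coil axial field,
base length 30 mm uniformly, with per-channel overrides in [28.5, 31.5] mm
for the uniformization experiment. Coils are evaluated as points by
default; a 4-point disc quadrature is available (`coil_radius`).

## Forward solution

*Stiffness.* Trilinear isoparametric hexahedra, one element per
non-background voxel, nodes deduplicated exactly, 8-point Gauss
quadrature. Local node order is lexicographic in (x, y, z) corner offsets
— lead-field signs depend on it and it is asserted in the tests. The
matrix is symmetric positive semi-definite with zero row sums (pure
Neumann); the gauge is zero-mean potential.

*Node-shifting.* Interface nodes (any node whose up-to-8 adjacent voxels,
background included, carry more than one label) move by
`2·factor·(t − x)`, where `t` is the mean over adjacent label groups of
each group's voxel-center centroid. On an already-planar interface the
construction is symmetric and the shift vanishes; at staircase corners
nodes move toward the minority compartment. Each displacement component is
bounded by `factor·h` and `factor < 0.5` is enforced; element validity
(positive corner Jacobians, which for a trilinear hexahedron are the
triple products of the incident edges) is checked on every mesh the
pipeline produces, and mesh volume is preserved to better than 2% on the
sphere phantom. The published factor 0.49 is the default. The exact rule
of the original meshing tool is not public; this is the package's own
smoothing of that kind, documented here precisely because lead fields are
sensitive to it.

*Source model.* The Venant load places balanced monopoles on the node
nearest the dipole and all nodes sharing an element with it. The monopole
vector is the minimum-norm solution of the hard constraints Σq = 0 and
Σq(r_k − r_dip) = **Q** (coordinates scaled by the voxel size for
conditioning), so the zeroth moment vanishes to machine precision and the
first moment is exact. Dipoles outside the mesh raise; dipoles outside
gray/white matter warn.

*Linear solves.* The contract is a relative residual ≤ 1e-8, enforced
after every solve. The default method is conjugate gradients with Jacobi
(diagonal) preconditioning applied to the consistent singular system with
a demeaned right-hand side; on the bundled meshes it converges in roughly
60–250 iterations. A cached sparse-LU factorization of the grounded system
("direct") is available; factorizations are released once transfer vectors
are built because they dominate memory.

*Secondary field.* For piecewise-constant conductivity the Biot–Savart
volume integral over −σ∇u equals a sum over conductivity-jump faces of
(σ⁺ − σ⁻)∫_S u n̂×(r−r′)/|r−r′|³ dS. This surface route is the default:
it avoids integrating the poorly resolved singular current swirl around
the Venant source (conductivity is locally constant there, so the source
region contributes no face) and evaluates the potential where the FEM
approximates it well. Faces are integrated with a 2×2 Gauss rule on the
bilinear surface patches. The element-centroid volume-current quadrature
is retained (`secondary_vectors(..., method="volume")`) as an independent
cross-check; at 0.5 mm resolution it underestimates the secondary
gradiometer signal by several percent, which the map-level
primary/secondary cancellation amplifies — the reason it is not the
default.

*Transfer vectors.* Per channel, t solves K t = w where w is the (row of
the) surface-integration matrix, projected onto the zero-mean subspace so
the Neumann system is consistent; for any balanced load b the secondary
signal is t·b, exactly the direct solve-and-integrate value by symmetry of
K (asserted to 1e-6 relative in the tests). Evaluating a dipole therefore
costs one small least-squares (the Venant load) and dot products.

*Validation.* The closed-form field outside a spherically symmetric
conductor and the spherical-harmonic potential of a homogeneous sphere are
implemented in `megfem.analytic` and are themselves tested against
structural identities (radial field component equals the primary's;
divergence- and curl-free outside; Neumann condition at the surface;
reduction to the unbounded-medium potential). The FEM pipeline reproduces
the closed-form gradiometer map of a tangential dipole in a layered sphere
(0.5 mm voxels) within RDM* ≤ 0.05 and |MAG_rel| ≤ 0.10 — measured values
are an order of magnitude smaller — and a radial dipole is silent to ≤ 1%
of the tangential map norm.

## Inverse solution

An unconstrained moving single-dipole fit. At a candidate position the
2–3-column lead field (unit-moment maps) gives the moment by linear least
squares; the cost is 1 − explained variance, where explained variance is
1 − ‖v − v̂‖²/‖v‖² clipped at 0. Position search is a hand-rolled downhill
simplex with reflection −1.0, expansion 2.0, contraction 0.5, at most 200
iterations, initial simplex size 10 mm (vertices at x₀ + 10 mm·eᵢ), a
0.01 mm simplex-diameter stop rule, ordering ties broken by insertion
order (deterministic), no restarts, and the best vertex accepted at the
cap; the result is never worse than the initial guess. Candidate positions
outside the brain compartment cost 2 (the RDM* maximum) so the simplex
stays well defined near boundaries. The initial guess is the known
physical source position, which is the study's protocol. Because the
penalty region is flat, convergence from far-off starts (several mm, with
most initial vertices outside the ~2 cm brain) can stall in displaced
local basins; within the protocol (truth-position starts, and one-step
offsets as tested) recovery is within one voxel. After the fit the moment
component along the coil-plane normal is zeroed, since the
mono-directional planar array does not constrain it.

## The bundled study

`default_study_config()` builds the desk-scale conditions: the ellipsoidal
~3 cm head at 0.8 mm mesh resolution (≈ 34k elements) with 0.8 mm skull
layers (radii 14 / 13.2 / 12.4 / 11.6 mm) so that all three layers are
resolved at that mesh size; two 5 mm defects 7 mm apart; a 23-position
shift line (12 full-step positions, eccentricities −1.96 … +1.08 relative
to defect 1); the 16-channel array; defect-conductivity sweep
{10⁻⁶, 0.004, 0.046, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0} S/m. The finer-grained
0.4 mm voxel default of the phantom module remains available for larger
runs. Ground truth for synthetic "measurements" is the defect model at the
physical agar conductivity 1.0 S/m and 130 µAmm; optional additive white
Gaussian noise is calibrated so that 20·log₁₀(rms signal / rms noise)
equals the configured SNR (40 dB reproduces the experimental regime), with
every random draw seeded. Reconstruction configurations: i-I (intact
data, intact model), d-I (defect data, intact model), d-D (defect data,
defect model). Intact and defect meshes share node numbering (defects only
relabel voxels), so fitted positions are comparable without interpolation.

The sensitivity analysis perturbs one tissue conductivity at a time
(compact bone, cancellous bone, gray matter, white matter; ±10, ±20,
±50%) in the reconstruction model only and reports fitted-position
displacement against the unperturbed baseline.

Because forward and truth models coincide in the i-I and d-D
configurations, those fits constitute an inverse-crime reference: their
near-exact recovery measures the fit machinery, not model adequacy. The
scientifically meaningful outputs are the *orderings* (d-I worse than i-I
under the defect; d-D restoring accuracy; displacement directed away from
the defect; matched defect conductivity minimizing the sweep error) and
the forward trends (magnitude change monotone in defect conductivity;
small positive change for an air-like defect; the defect-induced map
component opposing the intact topography). On this phantom the
under-defect position error of d-D fits as a function of the *model's*
defect conductivity is not monotone at intermediate values — wrong-model
fits land in displaced basins of nearly equal explained variance
(≈ 0.999) — while the matched conductivity is always the minimizer.

## What the synthetic data do and do not show

The generator emulates the geometry, conductivities, source protocol and
sensor array of a controlled skull-defect experiment, with exactly known
truth. It does not emulate biological variability (impedance drift around
an implant, tissue heterogeneity), co-registration error, environmental
noise beyond white Gaussian at a configured SNR, white-matter anisotropy
(an isotropic equivalent is used), or any specific animal's anatomy.
Passing tests therefore demonstrate the correctness and internal
consistency of the numerical pipeline and the qualitative defect physics;
they do not certify error magnitudes for any real head, which depend on
geometry not reproduced here (absolute effect sizes on this phantom — e.g.
the ≈ 44% magnitude drop at agar conductivity versus ≈ 20% in the animal
experiment this type of setup emulates — are geometry-dependent).

## Numerical choices and degenerate inputs

- Units: mm, S/m, µAmm, fT at the API; SI internally; conversions in
  `megfem.units`.
- Zero loads solve to zero potentials; zero-norm maps make RDM*/MAG_rel
  and explained variance undefined and raise.
- Defects that miss the skull raise; defects removing > 25% of the skull
  warn.
- A defect whose axis is parallel to the shift line has no eccentricity
  scale and raises.
- Quartiles use linear interpolation between order statistics; orientation
  angles are folded to [0°, 90°] because the fitted dipole sign is not
  identifiable.
- Label grids round-trip as raw int16 plus a JSON header; meshes and
  volumes export as legacy-ASCII VTK for inspection.

## Problem sizes

The bundled study grid (0.8 mm, ≈ 34k elements) builds a forward model in
a few seconds and runs the full reconstruction grid in minutes on one CPU;
the validation sphere (0.5 mm, ≈ 38k elements) takes comparable time.
These sizes were chosen as the package's default desk scale; every
component accepts finer grids (the phantom module's 0.4 mm default
reproduces the source imaging resolution the design targets) at
correspondingly higher cost.
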