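# Methods

This note records the models, parameter choices and numerical conventions
behind `limbuskit`, and what the synthetic test bed does and does not show
about real two-photon data.

## Imaging geometry and depth convention

Stacks are arrays of shape `(slices, rows, cols)` with a lateral pitch of
2 μm/pixel at 512 × 512 pixels per section and an axial step of 5 μm,
matching the trans-scleral acquisition the package is designed around.  The
eye surface is depth 0; slice *k* sits at `depth_origin + k·axial_step` μm.
The default scene spans depths 90–220 μm (27 slices) so that the aqueous
vein window (95–120 μm), the TM window (185–215 μm) and the SC window
(190–215 μm) coexist in one stack.  In-slice orientation is cornea on the
left, sclera on the right, with the TM band between them.

## Synthetic scene model

**TM microstructure.**  The porous band is carved from spatially correlated
Gaussian noise: a standard-normal field smoothed with a Gaussian whose
physical correlation length equals `beam_thickness_mean` (default 10 μm —
a few-pixel beam scale producing irregular interconnected pores between
fiber-like bright ridges).  Per slice, the pore/beam threshold is placed at
the order statistic matching the depth-interpolated porosity target, so the
realized pore fraction is exact to one voxel (well inside the ±0.02
construction tolerance).  Configurations whose TM cross-section is smaller
than ~4 correlation lengths per side (or under 500 pixels) cannot realize a
target reliably and are rejected.

**Calibrated presets.**  The intact-eye preset uses porosity knots 0.63 at
185 μm → 0.74 at 215 μm; the depressurized (equivalently "high-IOP")
preset is geometrically identical — same seed, same SC and vein paths —
with knots 0.44 → 0.59.  The SC lumen is an elliptical void (circular by
default, so the chord-mean equals the nominal diameter) whose diameter
profile rises from 48 μm at 190 μm depth to a 64.67 μm maximum at 207 μm
and falls to 58 μm at 215 μm; because the peak lies between the 205 and
210 μm slice planes, the *sampled* profile peaks one axial step from the
nominal depth with a value ≈64.2 μm.  The vein trunk runs 32 μm (95 μm
depth) → 43 μm (120 μm); a thinner 18 μm branch diverges from the trunk
below 104 μm depth, fast enough to be a separate component over most of
the measured window.  The trunk is the measured vessel; the branch
reproduces the branching morphology near the surface.

**Imaging model.**  Per-class signal strength (sclera and TM beams 1.0,
cornea 0.85, fluid voids 0) is attenuated by `exp(−depth/ℓ)` with
ℓ = 150 μm (a typical scattering length for collagenous ocular tissue —
signal at 215 μm is ~24 % of the surface value), blurred by an anisotropic
Gaussian PSF of σ = (1, 2) μm (lateral, axial), then sampled as Poisson
counts at `photon_scale` = 800 expected counts for full signal plus
Gaussian read noise of σ = 3 counts, rounded to integer counts.  Setting
`photon_scale = inf`, `read_sigma = 0` yields the noise-free expectation
used by exactness tests.  All randomness derives from a single integer
seed (documented default 20161228); label construction and rendering are
deterministic given it.

**What the generator does not emulate:** SHG/2PAF excitation physics,
detector nonlinearity, motion or refractive-index distortions, segmental
(circumferential) variation of the outflow pathway, and real pore-space
topology beyond a correlated-noise texture.  Passing recovery tests
therefore demonstrates that the *pipeline* is unbiased under the stated
imaging model, not that it is robust to every artifact of real data.

## Porosity pipeline

Per section inside the TM region of interest: a 1–99 percentile linear
stretch onto [0, 1] (monotone, so rank-based thresholds are unaffected),
then Otsu's threshold on a 256-bin gray histogram (between-class-variance
argmax; ties break toward the lower cut; the returned value is a bin edge,
strictly between the extremes), then pores = strictly-below-threshold
pixels and φ = pore pixels / valid pixels with valid = the whole ROI box.
One threshold per slice absorbs depth attenuation.  Degenerate
(near-constant) sections are reported as missing entries with a reason
rather than silently skipped.  On noise-free renders the estimate matches
ground truth to ≤0.01; on the noisy presets to ≤0.03.

## Lumen morphometry

A lumen is the largest below-threshold 8-connected component in the ROI,
subject to a minimum area of a 10 μm-diameter circle (smaller than any
reported lumen, larger than noise specks).  When the threshold is derived
automatically, a contrast guard rejects ROIs whose "dark" class mean
exceeds 0.25× the bright class mean: on a lumen-free patch Otsu simply
splits unimodal noise (dark/bright ratio ≈0.49 empirically, vs ≈0.03 with
a real void present), and such sections are reported as missing.  Diameter
is operationalized as the mean of *n* chords through the component
centroid at orientations *iπ/n* (default *n* = 5): each chord is the
extent of the mask along that line, sampled at quarter-pixel steps with
nearest-neighbour lookup (which already extends half a pixel beyond the
extreme pixel centres, so no further width correction is applied; residual
quantization is ~1 pixel).  Non-convex components (centroid outside the
mask) are measured with a warning.

## Reconstruction and meshing

Segmentation keeps voxels with intensity ≥ threshold (collagen is bright);
region growing retains the 6- or 26-connected component of a seed;
morphological editing applies open/close/fill-holes with anisotropic
voxel balls of a given physical radius.  Every step appends to a
provenance list that replays bit-identically against the source stack.

Meshing splits each tissue voxel into the 6 tetrahedra of the Kuhn
(Freudenthal) subdivision — all containing the cube's main diagonal, hence
conforming across shared faces with no bookkeeping — rather than a
surface-extraction approach, so tissue volume is conserved exactly and no
resampling error enters the FEM geometry.  Nodes sit at voxel corners;
x = col·pitch, y = row·pitch, z = depth.  Because voxel index order
(slice, row, col) maps to (z, y, x), tets are re-oriented positively in
physical space after coordinate mapping.  Boundary triangles are faces
used by exactly one tet, outward-ordered via the opposite vertex.
Pressure faces are those whose outward normal lies within `angle_tol`
(default 30°, wide enough to capture the non-planar TM inner surface) of
the load direction; the fixed set is a user predicate (default: the
scleral-side max-x face, since the constrained surface's extent is a
modeling choice), and fixed wins where both match.

## Finite-element model

Small-strain isotropic linear elasticity on constant-strain tetrahedra with
the TM defaults E = 162 Pa, ν = 0.48.  Geometry converts μm → m at
assembly so pressures in Pa give forces in N; displacements are reported
in μm.  Pressure loading is the consistent CST load p·A/3 per face vertex
along −n.  Dirichlet constraints are eliminated (reduced system), so fixed
dofs are exactly zero; besides whole-node fixing, individual dofs can be
constrained — needed to realize the textbook uniaxial patch state (tip
deflection pL/E for any ν requires a laterally free base).  The reduced
system is factorized once per sweep (SuperLU) and back-substituted per
pressure; the relative residual must be ≤1e-8, with a diagonally
preconditioned CG fallback at 1e-10.  The default sweep is 10…160 Pa in
10 Pa steps — the modeled IOP−EVP pressure drop range.

The model is deliberately linear even though p/E approaches 1 at the top
of the sweep (strains of order one): the analysis reproduces the linear
small-strain design, so reported deformations scale exactly linearly in
p/E and should be read as a linearized sensitivity, not a prediction of
finite-strain kinematics.  "Directional deformation" is the displacement
component along the load direction; its maximum is taken over absolute
values, since the sign convention of the plotted magnitude is arbitrary.

## Numerical choices and degenerate inputs

- Otsu ties and empty histogram valleys: any cut through an empty valley
  induces the same segmentation; the implementation returns the lowest
  optimal cut edge.
- Constant images raise a degenerate-image error (no threshold exists).
- Empty segmentations, out-of-mask seeds, empty pressure or fixed sets,
  zero-volume tets and the incompressible limit ν = 0.5 all raise typed
  errors rather than producing silent garbage.
- Stacks round-trip bit-exactly through 16-bit TIFF because rendered
  counts are integers; metadata travels in JSON sidecars.

## Problem sizes

The default scene is 27 × 512 × 512 voxels (≈7 M), generated and analyzed
in seconds.  FEM correctness is established on analytic meshes (bars,
blocks, ≈10²–10³ elements) where closed-form oracles exist, plus a
TM-subvolume model of ≈6 000 tets for the qualitative beam-deformation
check; the solver itself is sparse and scales to much larger meshes.

## Known limitations

- The chord-based diameter is a surrogate for unrecorded manual caliper
  protocols; other operationalizations (min/max Feret, equivalent-area
  diameter) would differ by up to the lumen's ellipticity.
- Porosity is an area ratio per section; no connectivity, tortuosity or
  permeability is derived.
- The linear FEM ignores geometric and material nonlinearity, fluid–
  structure interaction and contact; see above.
- The voxel mesher produces axis-aligned staircase boundaries; boundary
  normals are exact for the voxelized shape, not for a smoothed surface.
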