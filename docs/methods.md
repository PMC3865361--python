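# Methods

## The registration model

`featreg` implements a piecewise ("featurelet") deformable registration
for 3D radiotherapy volumes.  The moving image M (typically the planning
CT) is tiled into non-overlapping rectangular subvolumes of size A (the
featurelets, or megavoxels); each featurelet is registered by a pure
translation into a search region of size B ≥ A centred on its footprint
in the fixed image F (typically the CBCT), maximizing a patch-similarity
merit — normalized correlation (NC) or mutual information (MI).  The
accepted translations live on the lattice of featurelet centers and are
interpolated trilinearly to every voxel, yielding a dense deformation
field **d** used to propagate images and contours.

The model assumes rigidly pre-aligned inputs with identical grids (an
optional coarse exhaustive-NC global translation is provided as
plumbing), locally translational motion at the scale of one featurelet,
and axis-aligned identity orientations (anything else is rejected at
I/O, never silently reinterpreted).

### Sign convention

All displacement vectors are stored in the resampling (pull-back) sense:
the fixed-image voxel `v` corresponds to moving-image position
`v + d(v)`, in voxel units per array axis with the spacing carried
alongside.  Under this single convention

* warping needs no field inversion: `out(v) = in(v + d(v))` resamples
  the moving image or its contours directly onto the fixed grid,
* the interpolated field reproduces each accepted featurelet's
  displacement exactly at its center, and
* an estimated field is directly comparable with the phantom's analytic
  ground truth.

The per-featurelet optimizer internally searches the patch-translation
offset `o` (the featurelet content's movement into the fixed image) and
reports `d = −o`.

### Optimizer

Regular-step steepest ascent on the merit as a function of the three
translation components:

* gradient by central finite differences of the merit, probe ±0.5 voxel
  for NC and ±1.0 voxel for MI (the MI surface carries bin-quantization
  jitter whose amplitude rivals the 1-voxel slope; the wider baseline
  averages it out);
* advance by the current step length along the normalized gradient,
  starting at 0.05 voxel;
* multiply the step by the relaxation factor 0.5 whenever the gradient
  direction reverses, or whenever the search-region clamp blocks more
  than half of the attempted move (without the second rule a featurelet
  pressed against the clamp by a consistent gradient never terminates);
* converge when the step drops below 0.001 voxel; cap at 2000 iterations
  per featurelet, read as a per-featurelet budget;
* the offset is clamped so the translated patch stays inside the search
  region and within the symmetric budget (B − A)/2 + 1 voxels per axis.

Defaults (featurelet 15³, search 30³, steps 0.05/0.001, 2000 iterations)
are the configuration that proved robust for pelvic CT/CBCT at 4 mm
resolution.  Subvoxel sampling of the fixed image uses linear
interpolation with clamp-to-edge, so no artificial zero border biases
the merit.  The whole procedure contains no randomness: identical inputs
and configuration give bit-identical featurelet sets.

### Merit metrics and their estimators

NC is the Pearson correlation of the flattened patches, invariant to a
positive affine rescaling of either patch and to nothing weaker.  MI is
H(A) + H(B) − H(A,B) in nats from a plain joint histogram with 32 × 32
equal-width bins spanning each patch's own intensity range — the
simplest estimator, chosen so that test values are exactly reproducible
by direct counting.  MI is invariant under any bin-preserving monotone
remap of one patch; this asymmetry is the mechanism that lets MI drive
intermodality (CT–CBCT) registration where NC fails.  For the
*optimizer's* surface only, the candidate patch is binned with linear
partial-volume weights (Mattes-style), making the surface continuous in
a subvoxel translation; reported merits always use the plain histogram.

A flat patch (zero variance — e.g. the water background) has no defined
NC and zero marginal entropy; it is flagged *degenerate* with value 0
rather than raising, and is always rejected downstream.

### Merit restriction and interpolation

Misregistered featurelets must not mislead the interpolation, so a
featurelet is accepted only if its optimizer converged, its merit is
non-degenerate and the merit value reaches a threshold — a hard
threshold, by default NC ≥ 0.5 or MI ≥ 0.1 nats, both configurable.  The
MI default is deliberately permissive: the raw histogram estimator has a
chance-level bias of roughly (bins−1)²/2N ≈ 0.14 nats for a 15³
featurelet, so some uninformative featurelets pass; their displacements
are near zero in practice and the interpolation tolerates them.
Rejected lattice nodes are filled with the nearest accepted node's value
(the least-commitment smooth choice) before per-component trilinear
interpolation on the true featurelet-center lattice, including the
truncated edge featurelets' true centers; outside the lattice hull the
field clamps to the edge value.  If *every* featurelet is rejected the
pipeline stops with an explicit error suggesting threshold relaxation
rather than emitting an empty field.

## Evaluation metrics

* DSC = 2|V_d ∩ V_m| / (|V_d| + |V_m|) × 100 — the standard Dice
  coefficient on the 0–100 reporting scale.
* Hausdorff distance over surface voxels (foreground voxels with a
  face-adjacent background neighbour; the grid boundary counts as
  background), as the double max–min of Euclidean distances; in pixels
  by default, in mm on request since slices are anisotropic in the
  target application (4 mm).
* Structure volume (voxels, cc), center of mass (mm), center-of-mass
  shift against the reference, and unsigned percent volume change.
* Paired two-sided Wilcoxon signed-rank comparisons with zero
  differences dropped; the exact null distribution of the signed midrank
  sum is computed by a subset-sum dynamic programme for n ≤ 25 (valid
  under ties), the tie-corrected normal approximation beyond.  Labels:
  NS when p ≥ α, otherwise better/worse by the sign of the median
  difference under the metric's orientation; `++`/`--` marks p < α/5.

## The digital phantom

The synthetic module emulates a purpose-built deformable pelvis phantom:
a water-filled box holding an inflatable bladder balloon (volume
adjustable within 200–400 cc, default 250 cc), a rigid ~110 cc
prostate-shaped insert glued to it, a fixed rectum-like tube posterior
to the prostate, and lateral radio-opaque bone blocks.  The default grid
is 96×96×64 voxels at 4 mm (384×384×256 mm), a desk-scale analogue of
the physical 40×40×29 cm box preserving the featurelet/search size
ratio; structure sizes are solved by bisection on the voxelized shapes,
so the generated prostate measures 110 cc within voxelization error.
Intensity levels are HU-like (water 0, bladder fill 120, polystyrene
prostate −35, bead-filled rectum 200, bone 700) with seeded Gaussian
noise of sd 4.

Deformations are analytic and smooth, so the ground truth is known by
construction rather than by delineation: a radial bladder inflation with
Gaussian falloff (default linear scale 1.17, inflating the default
bladder to ≈ 380 cc — within the balloon's physical filling range), a
rigid prostate translation (default (12, 8, 0) mm ≈ 3.6 voxels) blended
to zero outside a plateau covering the insert, and an identically zero
field on the rectum dilated by one voxel.  The rectum is placed so both
components stay below half a voxel within one voxel of it; under
nearest-neighbour mask warping the rectum is then *exactly* invariant,
reproducing the reference condition DSC = 100 / Hausdorff = 0 of a
static structure.  The peak amplitude (≈ 5 voxels by default) is capped
at a configurable 7 voxels, within the (30−15)/2 + 1 displacement budget
of the default registration.

`deform_phantom` warps the noisy baseline volume, so the zero-parameter
deformation is the exact identity.  `make_benchmark_pair` instead
re-renders the deformed scene from the clean geometry and adds a fresh
seeded noise realization, emulating two independent acquisitions; without
this, the shared noise would correlate at the true alignment and flatter
the registration.

### The CBCT surrogate and the constructed NC worst case

`simulate_cbct_appearance` passes intensities through a strictly
monotone remap (verified numerically on the volume's range), multiplies
by a first-order multiplicative shading ramp along the in-plane diagonal
(default ±12%), and adds noise — geometry and masks untouched.  It is an
intensity surrogate only; scatter, beam hardening and reconstruction
artifacts of real CBCT are out of scope.

The default remap compresses soft tissue onto a large pedestal
(900 + 10·tanh((x+10)/25), plus a steep high-intensity branch keeping
bone high-contrast).  The construction targets the dissociation window
analytically: with clean moving-patch class contrast 2s and a
within-patch shading spread w (approximately uniform for a linear ramp),
NC at the true alignment ≈ s/√(s² + w²/12) while MI ≈ 0.69·(2s/w) nats
for two balanced classes.  The defaults give, for a prostate-edge
featurelet, NC ≈ 0.45 (below the 0.5 acceptance threshold, so the
NC-driven registration discards its soft-tissue featurelets and keeps
essentially the static bone) and MI ≈ 0.2 nats (accepted, with the MI
optimum at the true offset).  The measured outcome on the default
benchmark matches: MI raises prostate DSC from ≈ 61 to ≈ 74 while NC
leaves it unimproved — the featurelet_MI/featurelet_NC intermodality
dissociation, by the mechanism the metric invariances predict.

## Problem sizes and numerical choices

* Benchmark registrations run 245 featurelets of 15³ voxels on the
  96×96×64 grid; one NC run takes on the order of a minute on one core,
  MI about three (six merit evaluations of 3375 samples per iteration,
  typically a few hundred iterations per featurelet).
* Trilinear interpolation is exact at lattice nodes to 1e-9 against the
  direct weight formula; 1-node lattice axes are handled by duplicating
  the plane.
* Ties in Wilcoxon ranks use midranks doubled to integers for the exact
  DP; two-sided p = min(1, 2·min(P(W≤w), P(W≥w))).
* Mask binarization maps any nonzero voxel to 1 and is idempotent;
  Dice of two empty masks, Hausdorff of an empty mask, and the center of
  mass of an empty mask raise explicit errors.

## What passing tests do and do not show

The phantom's structures are homogeneous with sharp boundaries and its
deformations are smooth, low-amplitude and analytic.  Passing the
recovery criteria therefore demonstrates the correctness of the
machinery (partition, optimization, restriction, interpolation, warping,
scoring) under the stated conditions — not clinical-grade accuracy on
patient anatomy, where contrast is poorer, motion larger and
delineation itself uncertain.  Known limitations: translation-only
featurelets (no per-block rotation/scaling), no multi-resolution
pyramid, no field inversion or diffeomorphic regularization, no
Jacobian/harmonic-energy diagnostics, and the CBCT surrogate's
simplified artifact model.
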