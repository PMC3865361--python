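# featreg

Piecewise ("featurelet") deformable registration and contour-propagation
evaluation for 3D radiotherapy volumes.

In image-guided adaptive radiotherapy, contours delineated on the
planning CT must be transferred to cone-beam CT (CBCT) volumes acquired
at treatment time, where anatomy has deformed — the bladder fills, the
prostate shifts, organs at risk move.  After a rigid pre-alignment, a
deformable registration estimates a dense displacement field between the
two volumes; warping the planning contours through that field propagates
them to the anatomy of the day.  `featreg` provides such a registration,
the standard metrics used to judge it, and a digital deformable pelvis
phantom whose ground-truth deformation is known analytically, so the
whole pipeline is verifiable without any scan data.

## Method

The moving image is tiled into non-overlapping subvolumes of size A
(*featurelets*, default 15×15×15 voxels).  Each featurelet is registered
by a pure translation into a search region of size B (default
30×30×30) centred on its footprint in the fixed image, maximizing either

* **NC** — normalized cross-correlation (sharp within one modality), or
* **MI** — joint-histogram mutual information (robust across modalities,
  being invariant to any bin-preserving monotone intensity remap),

with a regular-step steepest gradient ascent (step length 0.05 → 0.001
voxels, relaxation 0.5 on gradient reversal, at most 2000 iterations per
featurelet).  A restriction on the final merit value (NC ≥ 0.5,
MI ≥ 0.1 nats by default) discards misregistered and degenerate
featurelets; the surviving displacements, living on the lattice of
featurelet centers, are interpolated trilinearly to every voxel.  The
field follows the resampling convention — the vector at fixed voxel `v`
points to the corresponding moving-image position `v + d(v)` — so images
and binary contour masks are warped onto the fixed grid with no field
inversion.

Contour agreement is quantified by the Dice similarity coefficient
DSC = 2|V_d ∩ V_m| / (|V_d| + |V_m|) × 100, the surface Hausdorff
distance H(A,B) = max(h(A,B), h(B,A)) with
h(A,B) = max_{a∈A} min_{b∈B} ‖a−b‖ (pixels or mm), volume and
center-of-mass statistics, and paired Wilcoxon signed-rank comparisons
(exact null distribution for n ≤ 25, tie-corrected normal approximation
beyond).

See `docs/methods.md` for the full model description, parameter
rationale, and what the synthetic phantom does and does not emulate.

## Worked example

Register the digital phantom's baseline scene (moving) to its deformed,
independently re-noised counterpart (fixed) and propagate the contours:

```python
import featreg as fr

fixed, moving = fr.make_benchmark_pair(seed=1)

config = fr.RegistrationConfig(metric="NC")
featurelets = fr.run_registration(moving.volume, fixed.volume, config)
controls = fr.filter_by_merit(featurelets, config)
field = fr.interpolate_field(controls, fixed.volume)

print(f"accepted {int(controls.valid.sum())}/{len(featurelets)} featurelets")
for name in ("bladder", "prostate", "rectum"):
    before = fr.dice_coefficient(moving.masks[name], fixed.masks[name])
    after = fr.dice_coefficient(
        fr.warp_mask(moving.masks[name], field), fixed.masks[name]
    )
    err = fr.field_error_voxels(field, fixed.truth_field, moving.masks[name])
    print(f"{name:9s} DSC {before:5.1f} -> {after:5.1f}   field error {err:.2f} voxels")
```

Output (about a minute on one core):

```
accepted 69/245 featurelets
bladder   DSC  77.1 ->  90.7   field error 1.44 voxels
prostate  DSC  60.7 ->  79.4   field error 1.41 voxels
rectum    DSC 100.0 -> 100.0   field error 0.06 voxels
```

Reading: before registration the inflated bladder and the shifted
prostate overlap their deformed references at DSC 77 and 61; the
NC-driven featurelet field raises both above 79 while its mean error
against the analytic ground-truth field stays below 1.5 voxels inside
every structure.  The rectum, fixed by construction (as a static
reference structure), keeps DSC 100.  With
`make_benchmark_pair(seed=1, intermodality=True)` the fixed volume gets
a CBCT-like appearance (monotone nonlinear remap, multiplicative
shading, noise); there the MI-driven registration still improves the
prostate contour while the NC-driven one does not — the
metric–modality dissociation that motivates offering both merits.

The same workflow is scriptable from the shell:

```bash
featreg phantom --out scene/ --seed 1
featreg register scene/fixed.mha scene/moving.mha --out reg/ --metric NC
featreg evaluate manifest.csv --out report/
```

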