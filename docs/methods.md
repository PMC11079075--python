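# Methods

## Adaptive gray-value thresholding

CBCT gray values are uncalibrated; the method assumes only that a scan's
histogram has (i) at most a few single-value spikes from air and
outside-field-of-view fill, and (ii) a single dominant, approximately
Gaussian soft-tissue mode, with bone/teeth forming a long diffuse tail.
Under those assumptions the bone truncation value is

```
x_b = x_s + d,   d = sigma_factor · σ,
```

with `x_s = µ` of a Gaussian `k/(√(2π)σ)·exp(−(x−µ)²/2σ²)` fitted by
least squares over a ±200 gray-unit window around the detected peak.

Parameters and defaults:

| parameter | default | unit | role |
|---|---|---|---|
| `bin_width` | 1 | gray units | histogram resolution; bins centered on `min + i·bin_width` |
| `median_kernel` | 5 | bins | removes spikes ≤ 2 bins wide; reflection at edges |
| `min_peak_width` | 5 | bins | width at half prominence a peak must reach |
| `min_peak_height_fraction` | 0.001 | — | peak height floor, relative to total voxels |
| `roi_halfwidth` | 200 | gray units | Gaussian fit window each side of the peak |
| `sigma_factor` | 3 | — | `d = sigma_factor·σ`; 3 is the calibrated operating point, exposed per scan/config |

Design choices where the procedure was genuinely open:

* **Peak "midpoint".** Detection returns the argmax bin of the qualifying
  peak; `x_s` is then taken from the fitted `µ` (default) because the fit
  pools the whole ROI and is stabler across scans. The raw-midpoint
  reading is available via `adaptive_threshold(..., x_s_from_fit=False)`.
* **Peak width** is measured at half prominence, in bins; ties between
  equal-height qualifying peaks resolve to the lower gray value, since soft
  tissue is darker than bone.
* **Fit initialization** `µ₀ = detected midpoint`, `σ₀ = roi_halfwidth/6`,
  `k₀` matched to the observed count at the midpoint; `σ` is bounded
  positive and a bound-limited or non-converged fit raises a distinct
  fit-failure error.
* **Degenerate histograms** (fewer bins than the peak-width floor, e.g. a
  constant volume) raise the no-peak error directly.
* **Fallback.** In the full preprocessing chain a no-peak or fit-failure
  condition falls back to the percentile baseline with a warning and a
  recorded reason code, so batch runs never abort on one pathological scan.

Known limitation: the height floor (0.1 % of voxels) interacts with the
gray range. Stretching the gray axis by much more than ~2× at unit bin
width flattens the per-bin peak height below the floor; such scans need a
proportionally coarser `bin_width`. The bundled manufacturer profiles stay
within 0.5–2× for this reason.

## Preprocessing chain

Fixed order: resample → threshold → clip → z-normalize.

* Resampling to isotropic 0.4 mm, linear for images and nearest for labels,
  with output dims `round(dim·spacing/target)`; border queries use
  nearest-neighbour extrapolation rather than a zero fill, which would bias
  border intensities.
* Clipping clamps to `[x_b, P99.5]` rather than deleting voxels — a grid
  image cannot drop voxels, and clamping preserves geometry for cropping.
  The upper percentile is computed on the resampled, unclipped volume
  (computing it after the lower clamp would tie the two bounds together).
* Normalization subtracts the post-clamp mean and divides by the population
  standard deviation; zero variance raises.

## Augmentation

Crop (96×160×160, uniform corner, undersized inputs symmetrically padded
with the image minimum / background label), per-axis mirror flip with
probability 0.5, then 0–16 cutout cubes of 12³ voxels set to zero
(uniform count, uniform corners, overlap allowed, labels untouched). One
`numpy` Generator seeded per sample drives all three ops in that fixed
order, so a single integer reproduces the transform bit-exactly.

## Losses

The combined objective is `w_CE·CE + w_Dice·Dice` with both weights 1.
The cross-entropy is class-averaged only — `−(1/C)·Σ_j Σ_i w_j G_ij log P_ij`
— and therefore scales with the number of voxels N; that form is kept as
the default, with a `per_voxel_mean` flag for a size-free variant. The soft
Dice per class is `Σ PG / (Σ P² + Σ G² + ε)` with ε = 1e-5 in the
denominator only, so a class absent from both prediction and truth
contributes a zero term rather than 0/0. Class weights default to 1.

## Evaluation metrics

Surfaces are mask voxels with a six-connected background neighbour (grid
boundary counts as background); distances are Euclidean between
surface-voxel centers in mm, honouring anisotropic spacing, computed with a
KD-tree. The Hausdorff distance is the exact maximum over both directed
distances (a percentile variant exists but is off by default, matching the
worst-case reading of the metric); the average surface distance pools both
directed nearest-distance sets, the common symmetric reading. mIoU excludes
background, which would otherwise inflate scores. A class absent from both
sides is "vacuous" (Dice 1, flagged, excluded from aggregates); absent from
one side gives Dice 0 with undefined distances. Per-tooth Dice is grouped
into positions T1–T8 by merging FDI quadrants. Aggregation reports
mean ± sample std (ddof 1) across cases plus an unweighted average row over
classes.

## Phantom generator

The phantom emulates the *histogram structure* the method assumes, not
anatomy: an ellipsoidal soft-tissue head in exact-constant air (the spike),
an optional constant outside-FOV cylinder (the second spike), two annular
bone arches, 32 ellipsoidal teeth on the arches labeled by FDI code, a
toroidal mandibular canal and an ellipsoidal maxillary sinus. Intensities
are class base values plus Gaussian noise — soft tissue N(300, 40), bone
+300, teeth +500, structure noise σ = 25 — followed by an affine
manufacturer transform. Defaults put bone ≥ 5 soft-tissue standard
deviations above the soft-tissue mean, so the modes are separated the way
well-exposed dental CBCT looks, and size the teeth to 2 % of the voxels,
the middle of the 1–3 % clinical imbalance range. In-plane tooth radii are
solved from the target fraction; geometry that cannot reach it raises with
a suggestion to enlarge the volume.

What the phantom does **not** model: metal artifacts, beam hardening,
motion blur, scanner noise correlation, anatomical shape realism. Passing
tests therefore demonstrate the algorithmic contracts (peak recovery,
equivariance, metric correctness, monotone degradation) — not clinical
segmentation accuracy, which requires real annotated scans.

The six bundled "manufacturer profiles" are invented affine presets
(scale 0.5–2.0, shifts −150 to +1200) representing inter-device gray-range
variability; they are synthetic stand-ins, not measurements of real
devices.

## Problem sizes and numerics

Default phantoms are 96×128×128 voxels at 0.4 mm — large enough for every
geometric structure to survive a 3-voxel erosion while keeping a full
phantom → preprocess → evaluate sweep at a few seconds per case. Gaussian
fits use `scipy.optimize.curve_fit` (Levenberg–Marquardt within bounds);
percentiles use linear interpolation between order statistics. Label
perturbations for metric testing are per-class morphology with a discrete
ball, or rigid integer shifts; erosion of a class is a subset of the
original, which guarantees Dice is monotone non-increasing in the erosion
radius.
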