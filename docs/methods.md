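# Methods

## Signal model and assumptions

A 2D cine PC-MRI acquisition encodes through-plane blood velocity into the
signal phase of a single slice: a voxel moving at velocity `v` acquires
phase `φ = π·v/v_enc`, where the velocity encoding `v_enc` (cm/s) is the
velocity mapping to ±π. `perfvel` assumes |v| < v_enc for perforating
arteries (no phase unwrapping is performed; cerebral perforator velocities
of 3–10 cm/s sit well inside the usual v_enc = 20 cm/s) and that the series
is retrospectively cardiac-gated into n ≥ 2 reconstructed heart phases.

Thermal noise is modeled as i.i.d. additive Gaussian noise of equal
standard deviation σ on the two quadrature channels. For a voxel with
magnitude signal A ≫ σ this makes the phase noise approximately
N(0, (σ/A)²), hence the velocity noise per frame

    σ_v = v_enc / (π · SNR_mag),  SNR_mag = A/σ,

and the per-frame velocity z-score SNR_v = v/σ_v approximately standard
normal in flow-free tissue. The test suite verifies this calibration
directly (Kolmogorov–Smirnov on a flow-free phantom, and a ~2.5% one-sided
exceedance rate at 1.96).

The noise level is estimated per voxel from the temporal variation of the
complex signal: σ̂ = sqrt(((std_t Re S)² + (std_t Im S)²)/2) with
S = M·exp(iφ), treating the two quadrature channels symmetrically. This is
unbiased in static tissue; in pulsatile voxels the physiological variation
inflates it, which the median filter (below) suppresses spatially.

## The detection statistic

Classification needs one velocity statistic per voxel, but SNR_v is a
per-frame map. `perfvel` reduces it with the plain temporal mean
(`temporal_statistic="mean"`, the default): a voxel passes the velocity
criterion when its cycle-averaged SNR_v exceeds T_n, i.e. when its mean
velocity exceeds T_n·σ_v. Because averaging n frames shrinks the null
standard deviation to 1/√n, this default is deliberately conservative: at
n = 14 the effective false-positive probability per voxel is ~1e−13, so
essentially every detection on tissue-like data is a real vessel, which is
consistent with the tens (not hundreds) of arteries typically reported on
~10⁴-voxel ROIs. The alternative `"mean_zscore"` multiplies the mean by √n,
giving the exact size-α z-test of zero mean velocity (α/2 one-sided); it
detects weaker vessels at the cost of a ~2.5% per-voxel false rate. The
choice is recorded in every provenance sidecar. The acquisition-dependent
scaling of T_n (number of heart phases, temporal resolution) is exposed as
an explicit multiplicative hook (`tn_scaling_factor`, scalar or callable)
with identity default, rather than a hard-coded formula; its value is
logged per run.

## Parameters

| Setting | Default | Units | Rationale |
|---|---|---|---|
| `alpha` | 0.05 | — | significance of T_n; 0.05 → T_n = 1.96 |
| `median_kernel_mm` | 10 | mm | noise/background smoothing scale; large vs vessels (≤0.3 mm), small vs field variations |
| `axes_ratio_max` | 2 | — | moment-ellipse elongation above which a cluster is in-plane |
| `dedup_distance_mm` | 1.2 | mm | multiple detections of one artery merge within this radius |
| `erosion_voxels` | 80 | passes | one-voxel ROI erosion passes; active only for semioval-center scans by default (motion-corrupted rim of automatic white-matter masks) |
| `ghost_percentile` | 0.3 | % | top magnitude percentile seeding ghost zones |
| `ghost_min_cluster_voxels` | 5 | voxels | bright speckle below this seeds no zone |
| `ghost_zone_scale_long` / `_perp` | 10 / 2 | ×equiv. diameter | zone growth along/perpendicular to the phase-encode axis; the paper-scale geometry of ghost displacement is acquisition-dependent, so both are configurable and logged |
| `connectivity` | 4 | — | edge-sharing components; subvoxel vessels rarely span diagonals, and 4-connectivity avoids merging adjacent distinct perforators |
| `temporal_statistic` | mean | — | see above |

The median filter kernel edge is `round(kernel_mm / mean in-plane spacing)`
forced odd (33 voxels at 0.3 mm spacing), with reflecting boundaries.

## Numerical choices

- **Median filtering.** Exact `scipy.ndimage.median_filter` for images up
  to 300² pixels; larger grids use a 12-bit quantized histogram rank median
  (reflect-padded), whose error is bounded by the image range/4095
  (≈0.01 cm/s on velocity maps) and which preserves constant images
  exactly. Both paths are deterministic.
- **Axes ratio.** Eigenvalues of the second central moments of the voxel
  centers, each floored at the unit-pixel variance 1/12, with
  ratio = sqrt(λmax/λmin). The floor makes single voxels and collinear sets
  well-defined (single voxel → 1.0, 1×6 bar → sqrt(35) ≈ 5.92); a contour
  ellipse is ill-defined for 1–5 voxel clusters.
- **Deduplication.** Greedy suppression in descending |v_mean| (ties broken
  by centroid row, then column): accepted detections are pairwise ≥ the
  distance threshold; every suppressed one lies within the threshold of an
  accepted, at-least-as-fast detection. Deterministic by construction.
- **Division guards.** Zero noise or SNR inside the ROI is replaced by the
  smallest positive ROI value with a logged warning rather than raising, so
  whole-folder batch runs never die on a degenerate voxel.
- **Erosion semantics.** `erosion_voxels` counts iterations of a one-voxel
  (3×3 cross) erosion, i.e. the width in voxels of the removed band.
- **Zero-vessel runs** report N_detected = 0 with v_mean and PI undefined
  (NaN in the summary); vessels whose trace mean is zero are dropped from
  pooling with a warning, never silently.
- **Trace extraction** uses the cluster's peak voxel (max |mean SNR_v|) —
  consistent with deduplication's highest-velocity semantics and least
  diluted by partial volume. The per-vessel table also reports per-vessel
  PIs for transparency, but the study PI is the pooled-trace PI.

## The phantom

`perfvel.phantom` synthesizes acquisitions voxel-wise in image space:
uniform static tissue (magnitude SNR 15 by default, matching 7T perforator
protocols), a smooth background phase plane removed by the correction step,
subvoxel vessels as complex mixing `(1−f)·tissue + f·blood·exp(iπv(t)/venc)`
— the physically correct partial-volume mechanism, which reproduces the
velocity underestimation expected for subvoxel arteries — and bright
in-plane vessels whose scaled complex replicas, shifted along the
phase-encode axis, emulate ghosting. The default study-like scene uses a
250 mm field of view at 0.3 mm in-plane resolution (832×832), 14 heart
phases, venc 20 cm/s, and 15 vessels with v₀ ∈ [3,7] cm/s sharing a
systolic raised-cosine waveform whose amplitude fixes the ground-truth
pooled PI at 0.5.

Not modeled: k-space acquisition (so no Gibbs ringing, no zero-filling
interpolation), coil sensitivities, gating jitter, bulk motion, velocity
aliasing, and flow-related enhancement. Passing phantom tests therefore
demonstrates the correctness of the statistical chain and the censoring
logic under the stated noise model, not robustness to every artifact of
clinical data.

## Problem sizes in the verification suite

Unit tests run on 16²–160² grids; null calibration uses a 256×256,
14-phase flow-free scene (~7×10⁵ velocity samples); parameter recovery runs
the full 832×832 scene over 20 seeds (about 90 s total); the acceptance
script repeats all of this from scratch in a few minutes on one CPU.

## Known limitations

- The DICOM reader supports classic single-frame series with M/P image-type
  tags and per-frame trigger times; enhanced multi-frame DICOM and 4D flow
  are out of scope. Vendor-specific v_enc locations vary — a configurable
  tag list is tried, then the `venc_cm_s` setting is required.
- The semioval-center erosion default (80 passes) presumes large automatic
  white-matter masks; small hand-drawn ROIs erode to empty, which raises a
  clear error rather than silently analyzing a sliver.
- The pooled PI's max−min statistic carries a small positive bias under
  per-frame velocity noise (visible as ~+0.05 at SNR_mag 15 with 15
  vessels); it shrinks with vessel count and SNR.
- No subvoxel centroid refinement or vein/artery discrimination beyond the
  flow-direction sign convention.
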