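# Methods

## Problem and measurement model

A 3D ONH scan is an ordered stack of `n_bscans` B-scans, each a grayscale
image whose columns are A-scans (axial depth profiles).  Row 0 is the
vitreous side; depth grows with the row index; all layer positions are
floating-point row coordinates.  Two boundaries define the edema: the
inner limiting membrane (ILM) above, and — because the retinal pigment
epithelium (RPE) is anatomically absent at the disc — a *hypothetical RPE
extension* below, reconstructed by spline fitting through the
peripapillary RPE and extrapolated across the disc.  The edema is the
region enclosed by the two surfaces, measured against a peripheral
reference plane shifted by a fixed pixel threshold.

All quantification is computed from the traces themselves: flattening is a
per-column shift, so the ILM height above the RPE (`rpe − ilm`) is
invariant under it, and no image is resampled.  This removes interpolation
bias from areas and makes ONHH from raw and flattened traces identical by
construction.

## Pipeline stages and parameters

**Denoising** (`preprocess`).  Median window 3 px, then Gaussian σ = 1.5 px,
both configurable and individually switchable; mirror padding at borders
so no artificial dark rim creates false gradients.  The filters are
deliberately simple: speckle is multiplicative and heavy-tailed, the
median removes the impulses, the Gaussian stabilises the threshold
crossings.  A 3×3 median via a jitted exchange network (bit-identical to
`scipy.ndimage.median_filter(mode="mirror")`, which is the fallback)
keeps full-volume runs fast.

**ILM stand-in** (`segmentation.segment_ilm`).  In clinical use the
device's own ILM segmentation is supplied (CSV of per-A-scan rows); the
built-in stand-in takes the first suprathreshold crossing from the top
(default 0.25 after smoothing) with sub-pixel linear interpolation.
Threshold crossing on a blurred edge sits systematically ~1 px above the
true boundary; this offset is common to all columns and cancels in the
area computation, because the peripheral reference is taken from the same
trace.

**Inner-layer masking** (`mask_upper_layers`).  Everything above
`ilm + offset` (default 25 px) is zeroed per column so the brightest
remaining pixels belong to the RPE band.  Columns with an invalid ILM use
the median valid ILM row; an ILM valid on under half the columns flags the
B-scan.

**RPE candidates** (`detect_rpe_candidates`).  The A-scans at 25% and 75%
of the width seed a search band (these anchors sit outside any realistic
disc).  From each anchor the band walks column by column, outward to its
edge and inward to the midline; per column the brightest of the top
`n_per_ascan = 3` pixels within ±15 rows of the running band center and
above an intensity floor (0.5 x mean anchor peak) is accepted and becomes
the new center; ties go to the smaller row for determinism.  Columns
below the floor contribute nothing — at the disc, where the RPE band is
absent, this opens a gap.  Candidate-bearing columns separated by more
than `gap_min = 20` columns form separate segments.  Both dark anchors
flag the B-scan.

**Spline order rule** (`choose_spline_order`).  Two or more segments mean
a disc gap is present: order 2 is used, because extrapolation across a
data gap is more stable at lower order (verified on gap phantoms: under
candidate noise σ = 2 rows the order-2 gap RMSE is smaller than order 3's).
A single uninterrupted segment uses order 3 to follow the full retinal
curvature.  Both mappings are configurable
(`segmentation.order_single_segment` / `order_multi_segment`).

**Least-squares spline** (`fit_rpe_spline`).  B-spline basis with
`n_knots = 5` interior knots, strictly uniform over the width and
continued at the same spacing beyond both ends (not clamped).  Plain
least squares is rank-deficient whenever the gap swallows a basis
function's support — precisely the extrapolation case that matters — so
the fit minimises `‖y − Bc‖² + λ‖D^{k+1}c‖²` with a difference penalty of
order `degree + 1` and small weight `λ = 1` (config
`segmentation.smooth_penalty`).  On a uniform knot grid the penalty's
null space contains all polynomials up to the spline degree, so exactly
polynomial data — e.g. the quadratic resting curvature of the RPE — is
reproduced exactly, gap included; the penalty only damps noise-driven
wiggle.  The unclamped knot vector matters: with repeated boundary knots
the coefficient sequence of a polynomial is no longer polynomial in the
index and the penalty would bias the fit.

**Quantification** (`quantify`).  Per B-scan: `rpe_row = median` of the
spline rows defines the flattened reference row; `h(a) = rpe(a) − ilm(a)`
is the ILM height; the peripheral reference is the pooled mean of `h` over
the leftmost and rightmost `ceil(0.10 · n)` A-scans (config
`quantify.margin_frac`; for a 15° field the 10% margins are safely outside
the disc).  The baseline plane sits `threshold_px = 20` axial pixels below
the reference (toward the RPE, `quantify.threshold_sign =
below_reference`); the opposite convention (above) is selectable.
The below-reference choice makes ONHV strictly positive in healthy eyes —
the threshold pedestal is part of the measure — which keeps control and
patient volumes on one scale.  Area, volume and height follow the formulas
in the README; flagged B-scans contribute zero area, and more than 20%
flagged B-scans abort the volume as unreliable.

## Phantom generator

`PhantomSpec` defaults emulate the target acquisition protocol: 145
B-scans x 384 A-scans x 496 depth px; pitches 3.9 µm axial, 15 µm lateral,
30 µm between B-scans (a 15°x15° field).  Geometry: the resting RPE is a
quadratic bowl (5e-4 px/px²); the ILM sits `retina_thickness_px` (default
100 px ≈ 390 µm) above it plus a radially symmetric Gaussian swelling
(amplitude in axial px, sigma in lateral px) and an optional disc-rim
bump; the RPE band is omitted inside `disc_radius_px` (default 55 px),
producing the disc gap.  Rendering anti-aliases all bands with linear
coverage ramps.  Noise: multiplicative gamma speckle with unit mean
(shape 4 — the standard first-order speckle approximation; unit mean keeps
expected intensities unbiased) followed by additive Gaussian noise
(σ = 0.02) and clipping to [0, 1].  Identical spec + seed gives
bit-identical volumes.

Default amplitude 40 px (≈ 156 µm peak elevation) represents a clearly
swollen disc; a zero-amplitude phantom reproduces the healthy-control
scale (baseline ONHH 0.39 mm against reported control means ≈ 0.40 mm).
Cohort sampling uses amplitude ranges 0–10 px for controls and 30–80 px
for patients by default — separated severity distributions; the
discrimination experiment in `evaluation.cohort_discrimination`
deliberately overlaps them (0–30 vs 15–80 px) so the AUC is informative
rather than trivially 1.

Ground truth: because both surfaces are analytic, the true ONHV/ONHH are
computed exactly by applying the quantification definition to the true
height field (`GroundTruth.true_onhv_mm3`), and a continuous closed form
(error functions for the Gaussian cap, flat pedestal, exact margin-tail
correction) is provided as an independent cross-check; the two agree to
well under 1%, and a 10x-grid trapezoid integration validates the closed
form to 0.1%.

What the phantom does **not** model: vascular shadowing, motion artifacts,
asymmetric edema, intraretinal layers beyond the two bright bands, and
device-specific intensity transfer curves.  Passing the phantom suite
therefore demonstrates the geometric and numerical correctness of the
algorithm under its stated model, not clinical performance; clinical
numbers (group means, AUC, percentile cutoffs from patient cohorts) are
not reproducible from synthetic data and are not claimed.

## Statistics

ICC is the single-measure *consistency* form ICC(3,1) =
`(MS_subjects − MS_error) / (MS_subjects + (k−1) MS_error)` from the
two-way ANOVA without replication (subjects random, sessions fixed).
Consistency was chosen over absolute agreement because repeated
acquisitions on one device are exchangeable repeats; the absolute-agreement
variant cannot be ruled out from the usual wording and is easy to add.
AUC is exhaustive pair counting with the half-tie convention — identical
to the normalised Mann-Whitney U, invariant under monotone transforms,
exactly antisymmetric under label flips.  Percentiles use the
linear-interpolation-between-closest-ranks rule for cross-implementation
determinism.  GEE models and rank correlations are intentionally out of
scope; `GroupedValues` carries the subject cluster id so the table can be
exported to a statistics environment that fits them.

## Evaluation designs and problem sizes

`onhquant.evaluation` (used by `scripts/acceptance.py` and the acceptance
tests) runs, at the full default grid:

* oracle closure on a 3x3x3 zero-noise grid (amplitude {0, 30, 80} px x
  sigma {25, 40, 60} px x thickness {80, 100, 120} px): worst ONHV error
  vs truth and worst ONHH error in axial px;
* noise robustness: 20 speckle seeds at amplitudes {0, 40, 80} px — ONHV
  CV and mean bias per amplitude;
* repeatability: 6 eyes (amplitudes spread 0–80 px) x 3 renders, ICC(3,1)
  for both measures — mirroring a 6-eye x 3-repeat clinical design;
* cohort discrimination: 8 + 8 eyes with overlapping severity, pipeline
  ONHV AUC and the 95th-percentile control cutoff with patient exceedance;
* spline-gap extrapolation on an exact and a noisy parabola (central half
  removed, 20 seeds);
* byte-level determinism of two identically configured runs.

Unit tests run the same operations on a reduced 25 x 128 x 160 grid with
proportionally scaled anatomy, which renders and segments in well under a
second per volume.

## Known limitations

* The ILM stand-in is a threshold detector; real devices use graph-based
  segmentation.  Supplying device traces via CSV bypasses it entirely.
* One spline per B-scan, no regularisation across B-scans; a slowly
  varying disc margin is therefore reconstructed independently per slice.
* The 20-px threshold is defined in native axial pixels, so scanners with
  different axial pitch measure slightly different physical pedestals;
  this mirrors the printed parameter rather than normalising it.
* Radially symmetric swelling only in the closed-form truth; arbitrary
  shapes are supported by the discrete truth but not by the erf formula.
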