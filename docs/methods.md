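# Methods

## Background and scope

Quantitative indocyanine-green fluorescence angiography (ICG-FA) reduces a
perfusion video to a fluorescence time curve (FTC) — the mean pixel
intensity inside a region of interest (ROI), frame by frame — and derives
scalar parameters from it. The parameter at the center of this package is
the **normalized maximum slope**,

```
max slope        = max_t ( F(t) − F(t − Δt) ) / Δt
normalized slope = max slope / (Fmax − F0)          [s⁻¹]
```

which divides the steepest inflow rate by the curve's intensity range so
that camera gain, distance and angle (which act approximately affinely on
intensity) cancel out.

Two independently developed quantification recipes computing this same
parameter are implemented as *algorithm profiles*:

* **AMS** — smooth the raw trace with a fourth-order low-pass Butterworth
  filter (0.1 Hz cutoff), then take the single highest adjacent-frame
  difference quotient over the entire recording;
* **CPH** — smooth with a Lanczos kernel average, locate the steepest
  adjacent-frame quotient, and report the ordinary-least-squares slope of
  intensity versus time over a 50-frame window (25 frames each side of that
  point, truncated at the recording ends).

Everything else (onset detection, peak, decay times, normalization) is
shared, so any cross-profile difference is attributable to the
(smoother, slope estimator) pair. The package also implements the
method-agreement statistics used to compare such profiles (Bland–Altman in
absolute and relative mode, proportional-bias regression, Shapiro–Wilk
gate, Mann–Whitney group comparison) and an ROI-displacement sensitivity
experiment. Because no clinical recordings are publicly available, all
analyses run on seeded synthetic recordings with analytically known ground
truth.

## Synthetic recordings

A recording is a noiseless perfusion curve plus additive noise, sampled at
`frame_rate` (default 25 fps — inferred from the equivalence of 50 frames
with roughly two seconds in this class of acquisitions; the true device
rate is not documented, so the value is configurable) for `duration`
(default 200 s, the minimum standardized acquisition length).

The noiseless curve has four phases: a flat baseline at `F0`; an inflow
rising to `Fmax` in one of two shapes; a single-exponential washout toward
`plateau_fraction × Fmax`; and optional saturation clipping. The two rise
shapes both admit closed-form ground truth:

* **linear** — a ramp of duration `T`; max slope `(Fmax−F0)/T`, normalized
  slope exactly `1/T`. The slope is discontinuous at onset and peak,
  emulating the abrupt arrival of a dye bolus.
* **logistic** — `F0 + (Fmax−F0)·σ(k(t−tc))` with steepness `k`;
  max slope `k(Fmax−F0)/4`, normalized slope exactly `k/4`. The center
  `tc` is placed `6/k` after the nominal onset, so the curve sits within
  0.25 % of its asymptotes at the nominal onset and at `onset + 12/k`,
  where washout takes over. The sigmoid's lower tail doubles as the
  baseline; the noiseless curve is therefore continuous everywhere, at the
  cost of the pre-onset signal sitting up to 0.25 % of the range above
  `F0`.

Noise is additive white Gaussian (`gaussian_sd`, in AU of the ROI-mean
trace) plus a sinusoid at `motion_frequency` with seeded random phase — a
surrogate for respiratory intensity modulation. Geometric frame motion is
deliberately out of scope (recordings with material motion are excluded
from this kind of study). Identical parameters and seed reproduce every
trace and frame stack bit for bit.

Frame stacks assign a perfusion curve to each pixel (a *curve field*),
generate an independent noisy realization per pixel, and record a manifest
of per-region ground truth; they exist so that ROI extraction and the
ROI-displacement experiment can run on spatially structured data.

## The benchmark cohort

`CohortSettings` freezes the study conditions for the in-silico
replication of the two-profile comparison:

* **n = 70 recordings**, 25 fps, 200 s.
* **Linear (abrupt-onset) inflow** with true normalized slope log-uniform
  over **0.02–0.15 s⁻¹**, the clinically reported span of this parameter.
  The linear shape is a deliberate choice: a bolus arrives abruptly, so
  the steepest segment of a real FTC sits at the onset knee. At that knee
  the two profiles genuinely disagree — a regression window anchored there
  necessarily includes sub-maximal points on the baseline side, while a
  zero-phase Butterworth filter rings at the slope discontinuity and
  slightly overshoots the true derivative. With a *smooth* (logistic)
  inflow instead, both estimators sit within a few percent of truth and
  the Butterworth attenuation actually dominates, reversing the sign of
  the mean difference; smooth-inflow cohorts are available but are not the
  default because they suppress the knee that real bolus kinetics have.
* **Heterogeneous baselines (5–20 AU) and intensity spans (60–140 AU)**.
* **Sensor noise 0.05 AU** on the ROI-mean trace. This is per-pixel sensor
  noise of a few AU divided by the square root of a typical ROI pixel
  count (a 10×10 mm ROI easily covers ~10⁴ pixels; a few-thousand-pixel
  ROI with σ_px ≈ 3–4 AU gives σ ≈ 0.05 AU). Trace-level noise levels of
  order 1 AU would be per-pixel magnitudes, not ROI-mean magnitudes, and
  would put spurious spikes into the lightly smoothed derivative.
* **Motion ripple 0.2 AU at 0.25 Hz** (≈15 breaths/min): mild residual
  modulation, consistent with the exclusion of visibly motion-corrupted
  recordings from the clinical workflow.
* **Washout 0.005–0.02 s⁻¹ toward 50–80 % of peak.**

Per-recording noise streams use child seeds spawned from the cohort seed,
so the cohort is a pure function of `(settings, seed)`.

Under these conditions the benchmark reproduces the qualitative clinical
findings: the pointwise-maximum profile reads higher on average (d > 0),
the inter-profile difference grows with the measurement magnitude
(positive proportional-bias slope, p ≪ 0.05), and the method-vs-method
regression slope falls in the 1.3–1.5 range. What passing this benchmark
shows is that the *mechanisms* (window averaging across the knee, filter
ringing/attenuation) behave as described; it does not certify the
magnitudes observed in any particular clinical dataset, whose raw-signal
structure (perfusion transients, drift, residual motion) the generator
does not emulate.

## Smoothing

**Butterworth.** `scipy.signal.butter` in second-order-section form —
at 0.1 Hz cutoff on 25 fps data the poles sit very close to the unit
circle and the transfer-function recursion loses ~6 digits that the
cascaded biquads retain. Zero-phase application (`sosfiltfilt`, reflected
padding) is the default so the filter does not delay the peak or the
maximum-slope location; a causal single pass (`sosfilt`, initial state at
the first sample) is available as `zero_phase=False`. Because the filter
is linear, the input is centered and scaled (by a power of two, exact in
binary floating point) before filtering and restored after; this keeps
the normalized slope affine-invariant to ~10⁻¹² instead of ~10⁻⁸.
Traces shorter than the padding warm-up are rejected.

**Lanczos.** The weight at frame offset `j ∈ [−radius, radius]` is
`L(j·a/radius)` with `L(x) = sinc(x)·sinc(x/a)`, i.e. the standard
Lanczos-`a` kernel stretched so its support covers `radius` frames per
side, normalized to unit sum. (Evaluating the un-stretched kernel at
integer offsets would degenerate to the identity, since `sinc` vanishes at
nonzero integers.) Defaults `radius = 12` (≈1 s at 25 fps), `a = 3`. At
the edges the kernel is truncated to the available samples and
renormalized, avoiding manufactured end transients that could masquerade
as maximum slopes. **These parameters are a reconstruction**: the original
software is only described as "averaging neighboring data points", with no
published window; the defaults are chosen to under-smooth visibly relative
to the 0.1 Hz Butterworth, reproducing the documented qualitative
contrast between the two implementations, and every parameter is exposed.

Both smoothers are linear with unit DC gain; the symmetric Lanczos kernel
additionally preserves affine signals exactly in the interior.

## Curve parameters

* **Onset t0** — "first intensity significantly above baseline" is
  concretized as the earliest sample exceeding *baseline mean +
  3 × baseline SD*, with baseline statistics over the first 5 s. Both the
  window and the multiplier are profile fields. A trace that never crosses
  the threshold (e.g. a constant recording) raises a no-onset error. The
  rule is affine-equivariant, which the normalization invariance relies on.
* **F0** — mean of the smoothed trace strictly before t0 (first sample if
  onset is at the first frame).
* **Peak** — global maximum of the smoothed trace, earliest tie wins (all
  argmax ties in the package break to the earliest index; deterministic
  and order-independent).
* **ttp** = t_max − t0, by construction exact in every record.
* **Mean slope** = (Fmax − F0)/(t_max − t0).
* **Decay times t90/t80** — earliest post-peak time at or below 90 %/80 %
  of Fmax; absence (curve never falls that far) is represented as a null
  value, not an error.
* **Slope estimators** — as defined above. The windowed estimator anchors
  on the smoothed trace's steepest adjacent-frame interval and centers the
  window on that interval's right endpoint; at the recording edges the
  window is truncated, never padded. An OLS slope is a
  (t_j − t_i)²-weighted mean of pairwise secant slopes, and every secant
  is a mean of adjacent-frame quotients, so the windowed estimate can
  never exceed the pointwise one on the same trace — this ordering is
  checked property-style across the whole cohort.
* **Normalization** uses the smoothed trace's Fmax and F0 (internal
  consistency: the slope came from the same curve). Whether the original
  implementations use raw or smoothed extrema is undocumented.

`quantify` refuses already-smoothed input: profiles own their smoothing,
and double smoothing would silently bias the slope.

## Trace extraction

The intensity of frame *i* is the arithmetic mean of the selected-channel
pixels inside the ROI; times are `i/frame_rate`. Pixel coordinates are
0-based, origin top-left, half-open (`[x, x+width) × [y, y+height)`).
Channel policy is explicit: `grayscale` (single-channel input only),
`green_channel`, or `luma` (ITU-R BT.601) for RGB overlays; stored pixel
values are used as-is, with no display mapping. ROIs are rectangles only;
out-of-bounds ROIs raise at extraction time.

## Agreement statistics

Differences are A − B (absolute mode) or 100·(A − B)/pairwise-mean
(relative mode; a zero pair mean raises an error naming the offending
cases rather than silently dropping them). d is the sample mean, s the
sample SD with n−1 (the one-sample t-test of the bias forces the n−1
convention), and the limits of agreement are d ± 1.96·s with the normal
1.96 hard-coded (not a t quantile — matching the convention of the
analysis this package reproduces). When s = 0 the bias p-value is
reported as undefined (`None`) rather than fabricated. Proportional bias
is OLS of the differences on the pairwise means; the method regression is
OLS of A on B. OLS inference (R², F, p) is delegated to statsmodels, the
Shapiro–Wilk gate, the t-test and the Mann–Whitney U comparison to scipy;
a constant response is short-circuited to slope 0, R² 0 (the ratio
0/0 a least-squares routine would otherwise produce is meaningless).
Group summaries are median (IQR) with linear-interpolation quartiles.

## ROI sensitivity

Around an original ROI, four inner ROIs are displaced ±`inner_offset`
along x then y, and four outer ROIs are displaced −2, −1, +1, +2 ×
`outer_offset` along a configurable conduit axis (default x), labelled
ROI2–ROI9 in that fixed order. Default offsets are half the ROI width
(inner) and twice the ROI width (outer). Each ROI is extracted and
quantified with the requested profile; deviations are
100·(value − original)/original. On a homogeneous field all deviations
are identically zero (checked); on graded fields the outer deviations
recover the analytic ratio of regional slopes.

## Problem sizes and numerical choices

The default test suite and the acceptance script use the cohort sizes the
analyses are defined with (70 recordings; 200 recordings for the
invariance sweep; 1000 random traces for the estimator oracles) and run in
well under a minute in total; frame-stack tests use small stacks
(≈20×60 px, ≤1500 frames) since per-pixel generation is the only
quadratic cost. Estimator tolerances: pointwise slope is bit-exact against
a brute-force scan; windowed slope matches closed-form normal equations to
10⁻¹⁰ relative; affine invariance holds to 10⁻⁹ relative (measured
~10⁻¹²); noiseless logistic recovery is within 2 % for k ≤ 1 s⁻¹ at
25 fps (measured ≤0.4 %, dominated by the discrete grid).

## Known limitations

* The Lanczos parameterization and the ROI-displacement offsets are
  reconstructions, not published facts about the original software.
* The generator emulates curve anatomy, not videos: no geometric motion,
  no vendor color overlays, no pharmacokinetic dye model, no camera
  optics. Conclusions about *mechanisms* transfer to real data;
  magnitudes need not.
* The windowed estimator's behavior depends on where its anchor lands;
  with heavy trace-level noise the anchor can leave the inflow phase
  entirely. The cohort's ROI-mean-scale noise keeps it anchored, which is
  the realistic regime, but per-pixel-scale noise on the trace would break
  both profiles in different ways.
* T₁/₂max and perfusion-pattern classification are out of scope; the
  group comparison implements the statistic only, not any clinical
  endpoint.
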