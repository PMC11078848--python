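# icgfa

Quantification of indocyanine-green fluorescence angiography (ICG-FA)
recordings, and measurement of the *agreement* between two independently
developed quantification algorithms.

Intraoperative ICG-FA visualizes tissue perfusion: a fluorescent dye bolus
is injected and a near-infrared camera records its arrival in the tissue of
interest (for example the gastric conduit before an esophageal
anastomosis). Software reduces the video to a **fluorescence time curve**
(FTC) — mean pixel intensity in a region of interest (ROI) per frame — and
derives perfusion parameters from it. The headline parameter is the
**normalized maximum slope**

```
max slope        = max_t ( F(t) − F(t−Δt) ) / Δt        [AU/s]
normalized slope = max slope / (Fmax − F0)              [1/s]
```

which is insensitive to camera gain, distance and angle because those act
affinely on intensity. Different software implementations of "the same"
parameter disagree in practice; this package implements two published
recipes as interchangeable **algorithm profiles** and the statistics to
compare them, for researchers evaluating quantitative perfusion software:

| profile | smoothing | slope estimator |
|---|---|---|
| `AMS` | 4th-order low-pass Butterworth, 0.1 Hz, zero-phase | pointwise maximum derivative over the whole recording |
| `CPH` | Lanczos neighborhood average (reconstruction; radius 12 frames, a = 3) | OLS slope over 50 frames (±25 around the steepest point) |

Also included: a seeded synthetic-recording generator (traces and frame
stacks) with closed-form ground truth, ROI-mean trace extraction from
TIFF/PNG stacks, Bland–Altman agreement analysis (absolute and relative,
limits of agreement d ± 1.96·s, bias t-test, proportional-bias
regression, Shapiro–Wilk gate, Mann–Whitney group comparison), and an
ROI-displacement sensitivity experiment. See `docs/methods.md` for the
model and every numerical choice.

## Worked example

```python
from icgfa import (
    AMS_PROFILE, CPH_PROFILE, AcquisitionParams, NoiseParams,
    PerfusionCurveParams, generate_trace, quantify,
)

curve = PerfusionCurveParams(
    baseline_intensity=10, peak_intensity=110, onset_time=10,
    rise_shape="linear", rise_duration_or_rate=20,   # true slope 1/20 = 0.05 1/s
    washout_rate=0.02, plateau_fraction=0.6,
)
rec = generate_trace(curve, AcquisitionParams(frame_rate=25, duration=120),
                     NoiseParams(seed=7))  # noiseless: isolates the algorithms
for profile in (AMS_PROFILE, CPH_PROFILE):
    p = quantify(rec.trace, profile)
    print(f"{profile.name}: t0={p.t0:.2f}s ttp={p.ttp:.2f}s "
          f"normalized max slope={p.normalized_max_slope:.4f} 1/s")
```

prints

```
AMS: t0=9.04s ttp=22.88s normalized max slope=0.0548 1/s
CPH: t0=9.60s ttp=20.48s normalized max slope=0.0275 1/s
```

The true value is 0.050 s⁻¹. The AMS profile reads ~10 % high — its
zero-phase Butterworth rings at the onset knee and the pointwise maximum
picks the overshoot — while the CPH profile reads ~45 % low, because its
steepest-point anchor sits at the knee and the 50-frame regression window
around it includes baseline points. That one curve summarizes why two correct implementations of the
same formula disagree systematically, and increasingly so for steeper
(better-perfused) curves.

## The analysis

The numbered scripts under `analysis/` replay the full study design on a
seeded 70-recording synthetic cohort (results land in `results/`):

```bash
python analysis/01_simulate_cohort.py --seed 1   # traces -> scratch/, manifest -> results/
python analysis/02_quantify_profiles.py          # both profiles -> results/parameters.csv
python analysis/03_agreement_analysis.py --plots # -> results/agreement.json (+ figures)
python analysis/04_roi_sensitivity.py            # -> results/roi_sensitivity.json
python analysis/05_outcome_groups.py             # -> results/group_comparison.json
```

With seed 1 the agreement step reports a mean absolute difference
d = +0.0145 s⁻¹ (AMS above CPH; limits of agreement −0.030 to 0.059), a
relative bias of +16 %, a positive proportional-bias slope (+0.43,
R² = 0.42, p ≈ 10⁻⁹) and a method regression AMS ≈ −0.003 + 1.31 × CPH
(R² = 0.76): the two profiles correlate strongly yet disagree
systematically, and the disagreement grows with the measured value.

The same pipeline is scriptable on real data: `icgfa extract` pulls an
ROI-mean trace out of a TIFF/PNG stack, `icgfa quantify` writes the
parameters CSV, `icgfa agree` the agreement report (`icgfa --help` lists
all subcommands).

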