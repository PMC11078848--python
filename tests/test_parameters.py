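"""Curve-parameter extraction and the two maximum-slope estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icgfa.errors import (
    DegenerateRangeError,
    InvalidInputError,
    InvalidIntervalError,
    InvalidParameterError,
    NoOnsetError,
)
from icgfa.parameters import (
    AMS_PROFILE,
    CPH_PROFILE,
    AlgorithmProfile,
    decay_times,
    detect_peak,
    detect_t0,
    max_slope_pointwise,
    max_slope_windowed,
    mean_slope,
    normalize_slope,
    quantify,
)
from icgfa.smoothing import SmoothingDescriptor
from icgfa.synthetic import (
    AcquisitionParams,
    NoiseParams,
    PerfusionCurveParams,
    generate_trace,
)
from icgfa.trace import FluorescenceTrace

from conftest import random_trace


def make_trace(values, frame_rate=1.0):
    values = np.asarray(values, dtype=float)
    return FluorescenceTrace(np.arange(values.size) / frame_rate, values, frame_rate)


class TestDetectT0:
    def test_step_after_noisy_baseline(self):
        rng = np.random.default_rng(12)
        n_base = 250  # 10 s at 25 fps
        values = np.concatenate([rng.normal(10, 1, n_base), np.full(250, 100.0)])
        trace = make_trace(values, frame_rate=25.0)
        t0 = detect_t0(trace, baseline_window=5.0, sd_multiplier=3.0)
        assert 10.0 <= t0 <= 10.5

    def test_constant_trace_has_no_onset(self):
        with pytest.raises(NoOnsetError):
            detect_t0(make_trace(np.full(300, 5.0), 25.0), 5.0, 3.0)

    def test_exact_step_frame_with_injected_baseline_jitter(self):
        # alternating +-0.1 jitter gives nonzero baseline SD; step at frame 150
        values = np.full(300, 10.0)
        values[:150] += 0.1 * (-1.0) ** np.arange(150)
        values[150:] = 100.0
        trace = make_trace(values, frame_rate=25.0)
        assert detect_t0(trace, 5.0, 3.0) == pytest.approx(150 / 25.0)

    def test_matches_first_exceedance_oracle(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.normal(20, 2, 200), np.linspace(20, 150, 200)])
        trace = make_trace(values, frame_rate=25.0)
        base = values[:125]
        threshold = base.mean() + 3.0 * base.std(ddof=1)
        oracle_idx = np.nonzero(values > threshold)[0][0]
        assert detect_t0(trace, 5.0, 3.0) == pytest.approx(oracle_idx / 25.0)


class TestDetectPeak:
    def test_earliest_tie_wins(self):
        assert detect_peak(make_trace([1, 5, 5, 2])) == (5.0, 1.0)

    def test_constant_trace_peaks_at_start(self):
        assert detect_peak(make_trace([3, 3, 3])) == (3.0, 0.0)

    def test_noiseless_logistic_peaks_at_rise_end(self):
        curve = PerfusionCurveParams(10, 110, 10, "logistic", 0.5, washout_rate=0.05)
        rec = generate_trace(curve, AcquisitionParams(25.0, 100.0), NoiseParams(seed=0))
        fmax, t_max = detect_peak(rec.trace)
        assert fmax == pytest.approx(110.0, abs=0.3)
        assert t_max == pytest.approx(curve.rise_end_time, abs=0.1)  # 10 + 12/k = 34 s


class TestMaxSlopePointwise:
    def test_brute_force_example(self):
        slope, at = max_slope_pointwise(make_trace([0, 1, 3, 6, 6]))
        assert (slope, at) == (3.0, 3.0)

    def test_constant_trace_zero_slope(self):
        slope, _ = max_slope_pointwise(make_trace([4, 4, 4]))
        assert slope == 0.0

    def test_strictly_decreasing(self):
        slope, at = max_slope_pointwise(make_trace([10, 9, 7]))
        assert (slope, at) == (-1.0, 1.0)

    def test_single_sample_traces_are_unconstructible(self):
        # the length >= 2 precondition is enforced by the trace container
        with pytest.raises(InvalidInputError):
            make_trace([1.0])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_equals_brute_force_scan(self, seed):
        trace = random_trace(np.random.default_rng(seed))
        slope, at = max_slope_pointwise(trace)
        dt = trace.dt
        quotients = [
            (trace.intensities[i + 1] - trace.intensities[i]) / dt
            for i in range(len(trace) - 1)
        ]
        best = max(range(len(quotients)), key=lambda i: (quotients[i], -i))
        assert slope == quotients[best]
        assert at == trace.times[best + 1]


class TestMaxSlopeWindowed:
    @pytest.mark.parametrize("half_width", [1, 5, 25])
    def test_affine_signal_returns_exact_slope(self, half_width):
        times = np.arange(200) / 25.0
        trace = FluorescenceTrace(times, 2.0 + 5.0 * times, 25.0)
        slope, _ = max_slope_windowed(trace, half_width)
        assert slope == pytest.approx(5.0, rel=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10_000), half_width=st.sampled_from([1, 5, 25]))
    def test_never_exceeds_pointwise(self, seed, half_width):
        trace = random_trace(np.random.default_rng(seed))
        windowed, _ = max_slope_windowed(trace, half_width)
        pointwise, _ = max_slope_pointwise(trace)
        assert windowed <= pointwise + 1e-12 * max(abs(pointwise), 1.0)

    def test_truncated_window_matches_ols_oracle(self):
        # steepest interval 10 frames from the start; half_width 25 truncates
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 1, 60)
        values[10] += 50.0  # max quotient at interval (9, 10) -> anchor point 10
        trace = make_trace(values, frame_rate=25.0)
        slope, (lo, hi) = max_slope_windowed(trace, 25)
        assert lo == 0
        t = trace.times[lo : hi + 1]
        y = trace.intensities[lo : hi + 1]
        design = np.column_stack([np.ones(t.size), t])
        coef = np.linalg.solve(design.T @ design, design.T @ y)
        assert slope == pytest.approx(coef[1], rel=1e-10)


class TestScalarHelpers:
    def test_normalize_slope_worked_example(self):
        assert normalize_slope(5.0, 110.0, 10.0) == pytest.approx(0.05)
        assert normalize_slope(0.0, 110.0, 10.0) == 0.0

    def test_normalize_degenerate_range_rejected(self):
        with pytest.raises(DegenerateRangeError):
            normalize_slope(5.0, 10.0, 10.0)

    def test_mean_slope_closed_form_and_guard(self):
        assert mean_slope(10.0, 30.0, 110.0, 10.0) == pytest.approx(5.0)
        with pytest.raises(InvalidIntervalError):
            mean_slope(30.0, 30.0, 110.0, 10.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_mean_slope_bounded_by_pointwise_max(self, seed):
        trace = random_trace(np.random.default_rng(seed), n_min=40)
        fmax, t_max = detect_peak(trace)
        if t_max == 0.0:
            return
        f_start = trace.intensities[0]
        if fmax <= f_start:
            return
        m = mean_slope(0.0, t_max, fmax, f_start)
        p, _ = max_slope_pointwise(trace)
        assert m <= p + 1e-9


class TestDecayTimes:
    def test_linear_decay_crossings(self):
        times = np.arange(0, 131)
        values = np.where(times < 30, times * (100 / 30.0), 100.0 - (times - 30))
        trace = FluorescenceTrace(times.astype(float), values, 1.0)
        out = decay_times(trace, t_max=30.0, Fmax=100.0, fractions=(0.9, 0.8))
        assert out[0.9] == pytest.approx(40.0)
        assert out[0.8] == pytest.approx(50.0)

    def test_absent_when_never_reached(self):
        trace = make_trace([0, 100, 99, 98])
        out = decay_times(trace, t_max=1.0, Fmax=100.0, fractions=(0.9,))
        assert out[0.9] is None

    def test_lower_fraction_crossed_later(self, small_cohort):
        for rec in small_cohort[:4]:
            fmax, t_max = detect_peak(rec.trace)
            out = decay_times(rec.trace, t_max, fmax, (0.9, 0.8))
            if out[0.9] is not None and out[0.8] is not None:
                assert out[0.8] >= out[0.9]


class TestQuantify:
    def test_linear_ramp_ams_near_truth(self, linear_ramp_recording):
        params = quantify(linear_ramp_recording.trace, AMS_PROFILE)
        assert params.normalized_max_slope == pytest.approx(0.05, rel=0.15)

    def test_cph_does_not_exceed_ams_on_ramp(self, linear_ramp_recording):
        ams = quantify(linear_ramp_recording.trace, AMS_PROFILE)
        cph = quantify(linear_ramp_recording.trace, CPH_PROFILE)
        assert cph.normalized_max_slope <= ams.normalized_max_slope

    def test_constant_recording_has_no_onset(self):
        trace = make_trace(np.full(400, 25.0), frame_rate=25.0)
        with pytest.raises(NoOnsetError):
            quantify(trace, AMS_PROFILE)

    def test_ttp_identity_holds_in_every_record(self, small_cohort):
        for rec in small_cohort:
            for profile in (AMS_PROFILE, CPH_PROFILE):
                p = quantify(rec.trace, profile)
                assert p.ttp == p.t_max - p.t0

    def test_smoothed_input_rejected(self, linear_ramp_recording):
        from icgfa.smoothing import butterworth_lowpass

        smoothed = butterworth_lowpass(
            linear_ramp_recording.trace, SmoothingDescriptor(method="butterworth")
        )
        with pytest.raises(InvalidInputError):
            quantify(smoothed, AMS_PROFILE)

    @pytest.mark.parametrize("k", [0.05, 0.2, 0.5, 1.0])
    def test_logistic_recovery_pointwise_on_raw(self, k):
        curve = PerfusionCurveParams(10, 110, 10, "logistic", k)
        duration = max(200.0, 10 + 12 / k + 20)
        rec = generate_trace(curve, AcquisitionParams(25.0, duration), NoiseParams(seed=0))
        slope, _ = max_slope_pointwise(rec.trace)
        fmax, _ = detect_peak(rec.trace)
        nms = normalize_slope(slope, fmax, 10.0)
        assert nms == pytest.approx(k / 4.0, rel=0.02)

    def test_divergence_grows_with_steepness(self):
        diffs = []
        for rise in (50.0, 20.0, 10.0):
            curve = PerfusionCurveParams(10, 110, 10, "linear", rise, washout_rate=0.01)
            rec = generate_trace(curve, AcquisitionParams(25.0, 120.0), NoiseParams(seed=0))
            ams = quantify(rec.trace, AMS_PROFILE).normalized_max_slope
            cph = quantify(rec.trace, CPH_PROFILE).normalized_max_slope
            diffs.append(ams - cph)
        assert diffs[0] < diffs[1] < diffs[2]


class TestAlgorithmProfile:
    def test_named_profiles_enforce_their_recipe(self):
        with pytest.raises(InvalidParameterError):
            AlgorithmProfile(
                name="AMS",
                smoothing=SmoothingDescriptor(method="lanczos"),
                slope_method="pointwise_max",
            )
        with pytest.raises(InvalidParameterError):
            AlgorithmProfile(
                name="CPH",
                smoothing=SmoothingDescriptor(method="lanczos"),
                slope_method="pointwise_max",
            )
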