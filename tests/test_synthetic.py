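"""Generator correctness: curve anatomy, seeding, noise statistics, ground truth."""

import numpy as np
import pytest

from icgfa.errors import InvalidParameterError
from icgfa.synthetic import (
    AcquisitionParams,
    NoiseParams,
    PerfusionCurveParams,
    generate_frame_stack,
    generate_trace,
    ground_truth_normalized_max_slope,
    noiseless_curve,
)


def linear_curve(**overrides):
    base = dict(
        baseline_intensity=10.0,
        peak_intensity=110.0,
        onset_time=10.0,
        rise_shape="linear",
        rise_duration_or_rate=20.0,
    )
    base.update(overrides)
    return PerfusionCurveParams(**base)


class TestNoiselessCurve:
    def test_linear_rise_hits_baseline_and_peak(self):
        rec = generate_trace(
            linear_curve(), AcquisitionParams(25.0, 60.0), NoiseParams(seed=0)
        )
        tr = rec.trace
        assert tr.intensities[np.searchsorted(tr.times, 10.0)] == pytest.approx(10.0)
        assert tr.intensities[np.searchsorted(tr.times, 30.0)] == pytest.approx(110.0)
        assert tr.intensities.max() == pytest.approx(110.0)
        # flat baseline before onset
        assert np.all(tr.intensities[tr.times < 10.0] == 10.0)

    def test_washout_decays_toward_plateau(self):
        curve = linear_curve(washout_rate=0.1, plateau_fraction=0.5)
        times = np.linspace(0, 300, 7501)
        values = noiseless_curve(curve, times)
        after = values[times > 30.0]
        assert np.all(np.diff(after) <= 1e-12)
        assert after[-1] == pytest.approx(55.0, rel=0.01)  # plateau = 0.5 * Fmax

    def test_logistic_is_continuous_and_spans_range(self):
        curve = linear_curve(rise_shape="logistic", rise_duration_or_rate=0.4)
        times = np.linspace(0, 60, 6001)
        values = noiseless_curve(curve, times)
        assert np.all(np.abs(np.diff(values)) < 1.0)  # no splice jumps
        assert values[0] == pytest.approx(10.0, abs=0.3)
        assert values.max() == pytest.approx(110.0, abs=0.3)


class TestGroundTruth:
    @pytest.mark.parametrize(
        "shape, param, expected",
        [
            ("linear", 20.0, 0.05),
            ("linear", 1.0, 1.0),
            ("logistic", 0.4, 0.1),
        ],
    )
    def test_closed_forms(self, shape, param, expected):
        curve = linear_curve(rise_shape=shape, rise_duration_or_rate=param)
        assert ground_truth_normalized_max_slope(curve) == pytest.approx(expected)

    @pytest.mark.parametrize("shape, param", [("linear", 8.0), ("logistic", 0.3)])
    def test_matches_dense_numerical_derivative(self, shape, param):
        curve = linear_curve(rise_shape=shape, rise_duration_or_rate=param)
        times = np.linspace(0, 100, 400_001)
        values = noiseless_curve(curve, times)
        num_max = np.max(np.diff(values) / np.diff(times)[0])
        expected = ground_truth_normalized_max_slope(curve) * 100.0  # range = 100 AU
        assert num_max == pytest.approx(expected, rel=1e-3)


class TestGenerateTrace:
    def test_seeded_determinism(self):
        curve = linear_curve()
        acq = AcquisitionParams(25.0, 60.0)
        noise = NoiseParams(gaussian_sd=2.0, motion_amplitude=1.0, motion_frequency=0.2, seed=7)
        a = generate_trace(curve, acq, noise).trace
        b = generate_trace(curve, acq, noise).trace
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_residual_noise_sd_matches_parameter(self):
        # 5000 frames: chi-square 99.99% band for the sample SD at sd=2
        curve = linear_curve()
        acq = AcquisitionParams(25.0, 200.0)
        rec = generate_trace(curve, acq, NoiseParams(gaussian_sd=2.0, seed=3))
        clean = noiseless_curve(curve, rec.trace.times)
        resid_sd = np.std(rec.trace.intensities - clean, ddof=1)
        assert 1.86 <= resid_sd <= 2.14

    def test_motion_artifact_is_a_sinusoid_of_requested_amplitude(self):
        curve = linear_curve()
        acq = AcquisitionParams(25.0, 60.0)
        rec = generate_trace(
            curve, acq, NoiseParams(motion_amplitude=3.0, motion_frequency=0.5, seed=1)
        )
        resid = rec.trace.intensities - noiseless_curve(curve, rec.trace.times)
        assert resid.max() == pytest.approx(3.0, rel=0.01)
        spectrum = np.abs(np.fft.rfft(resid[: 25 * 40]))
        freqs = np.fft.rfftfreq(25 * 40, 1 / 25.0)
        assert freqs[np.argmax(spectrum)] == pytest.approx(0.5, abs=0.05)

    def test_saturation_clipping(self):
        acq = AcquisitionParams(25.0, 60.0, intensity_ceiling=90.0)
        rec = generate_trace(linear_curve(), acq, NoiseParams(seed=0))
        assert rec.trace.intensities.max() == 90.0

    def test_rise_beyond_recording_end_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_trace(
                linear_curve(rise_duration_or_rate=100.0),
                AcquisitionParams(25.0, 60.0),
                NoiseParams(seed=0),
            )

    @pytest.mark.parametrize("kwargs", [{"frame_rate": -1.0}, {"duration": 0.0}])
    def test_invalid_acquisition_rejected(self, kwargs):
        base = dict(frame_rate=25.0, duration=60.0)
        base.update(kwargs)
        with pytest.raises(InvalidParameterError):
            AcquisitionParams(**base)

    def test_noise_sd_converges_with_frame_count(self):
        # residual SD approaches gaussian_sd as the recording grows
        curve = linear_curve()
        devs = []
        for duration in (40.0, 400.0):
            acq = AcquisitionParams(25.0, duration)
            rec = generate_trace(curve, acq, NoiseParams(gaussian_sd=1.0, seed=9))
            clean = noiseless_curve(curve, rec.trace.times)
            devs.append(abs(np.std(rec.trace.intensities - clean, ddof=1) - 1.0))
        assert devs[1] < devs[0]


class TestFrameStack:
    def test_uniform_field_matches_single_trace(self):
        curve = linear_curve()
        acq = AcquisitionParams(25.0, 60.0)
        stack = generate_frame_stack(
            lambda r, c: curve, acq, NoiseParams(seed=0), frame_shape=(4, 5)
        )
        single = noiseless_curve(curve, np.arange(acq.n_frames) / 25.0)
        for r in range(4):
            for c in range(5):
                np.testing.assert_allclose(stack.frames[:, r, c], single)

    def test_seeded_determinism(self):
        curve = linear_curve(onset_time=2.0, rise_duration_or_rate=10.0)
        acq = AcquisitionParams(25.0, 20.0)
        noise = NoiseParams(gaussian_sd=1.0, seed=5)
        a = generate_frame_stack(lambda r, c: curve, acq, noise, (3, 3))
        b = generate_frame_stack(lambda r, c: curve, acq, noise, (3, 3))
        assert a.frames.tobytes() == b.frames.tobytes()

    def test_two_region_manifest_records_both_truths(self):
        fast = linear_curve(rise_duration_or_rate=10.0)
        slow = linear_curve(rise_duration_or_rate=40.0)
        stack = generate_frame_stack(
            lambda r, c: fast if c < 3 else slow,
            AcquisitionParams(25.0, 60.0),
            NoiseParams(seed=0),
            frame_shape=(2, 6),
        )
        slopes = sorted(
            region["normalized_max_slope_true"] for region in stack.manifest["regions"]
        )
        assert slopes == pytest.approx([0.025, 0.1])
        assert sum(r["n_pixels"] for r in stack.manifest["regions"]) == 12

    def test_undefined_pixel_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_frame_stack(
                {(0, 0): linear_curve()},
                AcquisitionParams(25.0, 20.0),
                NoiseParams(seed=0),
                frame_shape=(2, 2),
            )
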