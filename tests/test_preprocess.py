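"""Preprocessing chain: filter responses, anomaly rule, normalization."""

import numpy as np
import pytest
from scipy import signal as sps

from bcgkit import (
    FilterSpec,
    PreprocessConfig,
    SignalRecording,
    apply_filter,
    baseline_correct,
    detect_anomalies,
    minmax_normalize,
    preprocess_pipeline,
    remove_anomalies,
)

FS = 100.0


def make_rec(channels, fs=FS, label="unlabeled") -> SignalRecording:
    channels = np.atleast_2d(np.asarray(channels, float))
    if channels.shape[0] < channels.shape[1]:
        channels = channels.T
    n = channels.shape[0]
    return SignalRecording(
        subject_id="t", label=label, sampling_rate_hz=fs,
        time_s=np.arange(n) / fs, channels=channels,
        channel_names=[f"ch{i}" for i in range(channels.shape[1])],
    )


def filtfilt_gain(spec: FilterSpec, freq_hz: float, fs: float = FS) -> float:
    """Oracle: magnitude response of the designed filter at one frequency
    (squared for the forward-backward pass)."""
    sos = spec.design_sos(fs)
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    gain = np.abs(h[0])
    return gain**2 if spec.zero_phase else gain


def tone(freq_hz, duration_s=20.0, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    return np.sin(2 * np.pi * freq_hz * t)


class TestApplyFilter:
    def test_highpass_removes_dc(self):
        rec = make_rec(np.full(2000, 5.0))
        out = apply_filter(rec, FilterSpec("highpass", 1.0))
        interior = out.channels[200:-200, 0]
        assert np.max(np.abs(interior)) < 1e-6 * 5.0

    def test_inband_tone_passes_cascade(self):
        """A 10 Hz tone survives HP 1 Hz + clamped LP within 5%, matching the
        designed filters' frequency response."""
        rec = make_rec(tone(10.0))
        out = apply_filter(rec, FilterSpec("highpass", 1.0))
        with pytest.warns(UserWarning, match="clamped"):
            out = apply_filter(out, FilterSpec("lowpass", 50.0))
        # RMS-based amplitude: sample peaks of a 10 Hz tone on a 100 Hz grid
        # never reach the true crest
        amp = np.sqrt(2.0) * np.std(out.channels[500:-500, 0])
        assert amp == pytest.approx(1.0, rel=0.05)
        expected = (filtfilt_gain(FilterSpec("highpass", 1.0), 10.0)
                    * filtfilt_gain(FilterSpec("lowpass", 50.0), 10.0))
        assert amp == pytest.approx(expected, rel=0.01)

    def test_outofband_tone_attenuated(self):
        rec = make_rec(tone(0.2, duration_s=40.0))
        out = apply_filter(rec, FilterSpec("highpass", 1.0, order=4))
        amp = np.max(np.abs(out.channels[1000:-1000, 0]))
        assert amp < 0.1
        assert filtfilt_gain(FilterSpec("highpass", 1.0, order=4), 0.2) < 0.1

    def test_linearity(self, rng):
        x = rng.normal(size=(3000, 1))
        y = rng.normal(size=(3000, 1))
        a, b = 2.5, -1.3
        spec = FilterSpec("highpass", 1.0)
        fx = apply_filter(make_rec(x), spec).channels
        fy = apply_filter(make_rec(y), spec).channels
        fxy = apply_filter(make_rec(a * x + b * y), spec).channels
        assert np.allclose(fxy, a * fx + b * fy, rtol=1e-8, atol=1e-10)

    def test_zero_phase_introduces_no_lag(self):
        x = tone(5.0, duration_s=30.0)
        out = apply_filter(make_rec(x), FilterSpec("highpass", 1.0)).channels[:, 0]
        xc = np.correlate(x - x.mean(), out - out.mean(), mode="full")
        lag = np.argmax(xc) - (len(x) - 1)
        assert lag == 0

    def test_cutoff_at_nyquist_without_clamp_raises(self):
        rec = make_rec(tone(10.0))
        with pytest.raises(ValueError):
            apply_filter(rec, FilterSpec("lowpass", 50.0), clamp=False)

    def test_short_recording_refused(self):
        rec = make_rec(np.zeros(10))
        with pytest.raises(ValueError, match="too short"):
            apply_filter(rec, FilterSpec("highpass", 1.0))

    def test_nonuniform_recording_refused(self):
        rec = make_rec(np.zeros(100))
        rec.time_s = rec.time_s**1.01
        with pytest.raises(ValueError, match="not uniformly sampled"):
            apply_filter(rec, FilterSpec("highpass", 1.0))

    def test_time_axis_untouched(self):
        rec = make_rec(tone(10.0))
        out = apply_filter(rec, FilterSpec("highpass", 1.0))
        assert np.array_equal(out.time_s, rec.time_s)


class TestDetectAnomalies:
    def test_constant_channel_yields_no_flags(self):
        mask = detect_anomalies(make_rec(np.full(100, 3.0)))
        assert mask.n_flagged == 0

    def test_single_spike_flagged_exactly(self):
        """99 zeros and one 100: mean 1, std ~9.95, threshold ~20.9, so the
        spike alone is flagged."""
        x = np.zeros(100)
        x[42] = 100.0
        mask = detect_anomalies(make_rec(x), k=2.0)
        assert mask.threshold_per_channel[0] == pytest.approx(20.8997487, abs=1e-4)
        assert mask.n_flagged == 1
        assert mask.flags[42, 0]

    def test_huge_k_flags_nothing(self, rng):
        mask = detect_anomalies(make_rec(rng.normal(size=500)), k=1e9)
        assert mask.n_flagged == 0

    def test_flags_invariant_under_constant_shift(self, rng):
        x = rng.normal(size=500)
        m1 = detect_anomalies(make_rec(x))
        m2 = detect_anomalies(make_rec(x + 17.3))
        assert np.array_equal(m1.flags, m2.flags)

    def test_rule_is_one_sided(self):
        x = np.zeros(100)
        x[10] = -100.0  # large negative excursion is not flagged
        mask = detect_anomalies(make_rec(x))
        assert mask.n_flagged == 0


class TestRemoveAnomalies:
    def test_zero_flags_is_identity(self, rng):
        rec = make_rec(rng.normal(size=200))
        mask = detect_anomalies(rec, k=1e9)
        out = remove_anomalies(rec, mask)
        assert np.array_equal(out.channels, rec.channels)

    def test_interior_flag_linear_midpoint(self):
        x = np.array([1.0, 50.0, 3.0] + [0.0] * 97)
        rec = make_rec(x)
        mask = detect_anomalies(rec, k=2.0)
        assert np.array_equal(np.flatnonzero(mask.flags[:, 0]), [1])
        out = remove_anomalies(rec, mask, mode="interpolate")
        assert out.channels[1, 0] == pytest.approx(2.0)

    def test_drop_mode_shortens_and_breaks_uniformity(self):
        x = np.zeros(100)
        x[[5, 50]] = 100.0
        rec = make_rec(x)
        mask = detect_anomalies(rec, k=2.0)
        out = remove_anomalies(rec, mask, mode="drop")
        assert out.n_samples == 98
        assert not out.is_uniform
        with pytest.raises(ValueError):
            apply_filter(out, FilterSpec("highpass", 1.0))

    def test_all_flagged_raises(self):
        rec = make_rec(np.arange(10.0))
        mask = detect_anomalies(rec)
        mask.flags[:] = True
        with pytest.raises(ValueError):
            remove_anomalies(rec, mask)


class TestBaselineCorrect:
    def test_linear_ramp_removed(self):
        n = 6000
        ramp = np.linspace(0.0, 10.0, n)
        out = baseline_correct(make_rec(ramp))
        interior = out.channels[1000:-1000, 0]
        assert abs(interior.mean()) < 1e-3 * 10.0

    def test_5hz_tone_preserved(self):
        out = baseline_correct(make_rec(tone(5.0, 30.0)))
        amp = np.max(np.abs(out.channels[500:-500, 0]))
        assert amp == pytest.approx(1.0, rel=0.05)
        assert filtfilt_gain(FilterSpec("highpass", 0.5), 5.0) == pytest.approx(1.0, rel=0.01)

    def test_zero_signal_stays_zero(self):
        out = baseline_correct(make_rec(np.zeros(1000)))
        assert np.allclose(out.channels, 0.0)


class TestMinmaxNormalize:
    def test_three_point_example(self):
        out = minmax_normalize(make_rec([-2.0, 0.0, 2.0]))
        assert np.allclose(out.channels[:, 0], [0.0, 0.5, 1.0])

    def test_constant_channel_maps_to_zeros(self):
        out = minmax_normalize(make_rec(np.full(50, 7.0)))
        assert np.all(out.channels == 0.0)

    def test_range_is_exactly_unit(self, rng):
        out = minmax_normalize(make_rec(rng.normal(size=300)))
        assert out.channels.min() == 0.0
        assert out.channels.max() == 1.0

    def test_idempotent_on_nonconstant_channels(self, rng):
        rec = make_rec(rng.normal(size=300))
        once = minmax_normalize(rec)
        twice = minmax_normalize(once)
        assert np.allclose(once.channels, twice.channels, atol=1e-15)


class TestPipeline:
    def test_output_bounded_in_unit_interval(self, rng):
        rec = make_rec(np.cumsum(rng.normal(size=(4000, 2)), axis=0) * 0.01
                       + rng.normal(size=(4000, 2)))
        out = preprocess_pipeline(rec)
        assert out.channels.min() >= 0.0
        assert out.channels.max() <= 1.0

    def test_spike_suppressed_below_recomputed_threshold(self, rng):
        x = rng.normal(0, 0.1, size=5000)
        x += np.sin(2 * np.pi * 7.0 * np.arange(5000) / FS)
        spike_at = 2500
        x[spike_at] += 50.0
        out = preprocess_pipeline(make_rec(x))
        v = out.channels[:, 0]
        assert v[spike_at] <= v.mean() + 2.0 * v.std()

    def test_stage_order_is_fixed(self):
        with pytest.raises(ValueError, match="fixed"):
            PreprocessConfig(stage_order=("lowpass", "highpass", "anomaly",
                                          "baseline", "normalize"))

    def test_stage_log_recorded(self, rng):
        out = preprocess_pipeline(make_rec(rng.normal(size=2000)))
        stages = [s["stage"] for s in out.meta["preprocess_stages"]]
        assert stages == ["highpass", "lowpass", "anomaly", "baseline", "normalize"]
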