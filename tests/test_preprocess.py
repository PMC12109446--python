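import numpy as np
import pytest

from gaitkit.preprocess import (
    FilterConfig,
    Normalizer,
    kalman_smooth,
    lowpass,
    preprocess_recording,
    select_channels,
)


def kalman_oracle(series, q, r):
    """Step-by-step scalar random-walk Kalman recursion (reference)."""
    x, p = series[0], r
    out = [x]
    for y in series[1:]:
        p = p + q
        k = p / (p + r)
        x = x + k * (y - x)
        p = (1 - k) * p
        out.append(x)
    return np.asarray(out)


def fitted_amplitude(signal, freq_hz, fs_hz):
    """Least-squares amplitude of a single tone."""
    t = np.arange(len(signal)) / fs_hz
    design = np.column_stack(
        [np.sin(2 * np.pi * freq_hz * t), np.cos(2 * np.pi * freq_hz * t)]
    )
    coef, *_ = np.linalg.lstsq(design, signal, rcond=None)
    return float(np.hypot(*coef))


class TestKalman:
    def test_constant_series_is_fixed_point(self):
        out = kalman_smooth(np.array([5.0, 5, 5, 5]), q=0.3, r=2.0)
        np.testing.assert_allclose(out, 5.0)

    def test_tiny_measurement_noise_passes_input_through(self):
        x = np.sin(np.arange(30))
        out = kalman_smooth(x, q=1.0, r=1e-12)
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_reduces_variance_of_alternating_series(self):
        x = np.tile([0.0, 1.0], 25)
        out = kalman_smooth(x, q=0.01, r=1.0)
        assert np.var(out) < np.var(x)

    @pytest.mark.parametrize("n", [1, 7, 100, 1000])
    def test_matches_recursion_oracle(self, rng, n):
        x = rng.standard_normal(n)
        q, r = 10 ** rng.uniform(-3, 0), 10 ** rng.uniform(-2, 1)
        np.testing.assert_allclose(
            kalman_smooth(x, q, r), kalman_oracle(x, q, r), atol=1e-12
        )

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            kalman_smooth(np.array([1.0, np.nan]), q=0.1, r=0.1)
        with pytest.raises(ValueError):
            kalman_smooth(np.array([1.0, 2.0]), q=0.0, r=0.1)
        with pytest.raises(ValueError):
            kalman_smooth(np.array([]), q=0.1, r=0.1)


class TestLowpass:
    def test_passband_tone_preserved(self):
        t = np.arange(500) / 50.0
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass(x, cutoff_hz=10, order=4, fs_hz=50)
        assert fitted_amplitude(y, 1.0, 50) == pytest.approx(1.0, rel=0.01)

    def test_stopband_tone_suppressed(self):
        t = np.arange(500) / 50.0
        x = np.sin(2 * np.pi * 20.0 * t)
        y = lowpass(x, cutoff_hz=10, order=4, fs_hz=50)
        assert fitted_amplitude(y, 20.0, 50) < 0.1

    def test_dc_gain_is_unity(self):
        y = lowpass(np.full(200, 3.7), cutoff_hz=10, order=4, fs_hz=50)
        np.testing.assert_allclose(y, 3.7, atol=1e-9)

    def test_zero_phase_keeps_pulse_centered(self):
        x = np.zeros(201)
        x[100] = 1.0
        y = lowpass(x, cutoff_hz=8, order=4, fs_hz=50)
        assert int(np.argmax(y)) == 100

    def test_preserves_length(self, rng):
        x = rng.standard_normal(333)
        assert len(lowpass(x, 10, 4, 50)) == 333

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass(np.zeros(10), cutoff_hz=25.0, order=4, fs_hz=50)


class TestChannelSelection:
    def test_default_exclusion_keeps_six_informative_channels(self, clean_recording):
        out = select_channels(clean_recording)
        assert out.channel_names == ("Ax", "Ay", "Gy", "Gz", "Yaw", "Roll")

    def test_empty_exclusion_is_identity(self, clean_recording):
        out = select_channels(clean_recording, excluded=set())
        assert out.channel_names == clean_recording.channel_names

    def test_excluding_everything_rejected(self, clean_recording):
        with pytest.raises(ValueError):
            select_channels(clean_recording, excluded=set(clean_recording.channel_names))

    def test_unknown_channel_rejected(self, clean_recording):
        with pytest.raises(ValueError):
            select_channels(clean_recording, excluded={"Qx"})


class TestPipeline:
    def test_preserves_length_and_labels(self, noisy_recording):
        out = preprocess_recording(noisy_recording)
        assert out.n_samples == noisy_recording.n_samples
        np.testing.assert_array_equal(out.stance_ref, noisy_recording.stance_ref)
        assert len(out.channel_names) == 6

    def test_filtering_is_nearly_idempotent(self, noisy_recording):
        cfg = FilterConfig()
        once = preprocess_recording(noisy_recording, cfg)
        twice = preprocess_recording(once, FilterConfig(excluded_channels=frozenset()))
        for name in once.channel_names:
            rms = np.sqrt(np.mean(once.channels[name] ** 2))
            delta = np.sqrt(
                np.mean((twice.channels[name] - once.channels[name]) ** 2)
            )
            assert delta < 0.01 * rms

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(kalman_process_var=0.0)
        with pytest.raises(ValueError):
            FilterConfig(lowpass_order=0)


class TestNormalizer:
    def test_zscore_uses_training_statistics(self, noisy_recording):
        norm = Normalizer.fit([select_channels(noisy_recording)])
        out = norm.transform(select_channels(noisy_recording))
        for name in out.channel_names:
            assert float(np.mean(out.channels[name])) == pytest.approx(0.0, abs=1e-9)
            assert float(np.std(out.channels[name])) == pytest.approx(1.0, rel=1e-6)
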