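import numpy as np
import pytest

from p300adapt.containers import ContinuousRecording, ContractError, EpochSet, EventMarker, MontageError
from p300adapt.preprocessing import (
    ConfigurationError,
    PreprocConfig,
    bandpass_filter,
    baseline_correct,
    extract_epochs,
    preprocess_recording,
    resample_epochs,
)


def recording_with_sine(freq, seconds=60, fs=250.0, channels=("Pz",)):
    t = np.arange(int(seconds * fs)) / fs
    sig = np.sin(2 * np.pi * freq * t)
    data = np.tile(sig[:, None], (1, len(channels)))
    return ContinuousRecording(data, fs, list(channels))


class TestBandpass:
    def test_passband_sine_survives(self):
        rec = bandpass_filter(recording_with_sine(10.0))
        mid = rec.samples[1250:-1250, 0]
        assert np.abs(mid).max() >= 0.9

    def test_stopband_sine_attenuated(self):
        rec = bandpass_filter(recording_with_sine(40.0))
        mid = rec.samples[1250:-1250, 0]
        assert np.abs(mid).max() <= 0.1

    def test_zero_in_zero_out(self):
        rec = ContinuousRecording(np.zeros((5000, 2)), 250.0, ["Pz", "Cz"])
        np.testing.assert_array_equal(bandpass_filter(rec).samples, 0.0)

    def test_band_above_nyquist_rejected(self):
        rec = recording_with_sine(10.0, seconds=2, fs=100.0)
        with pytest.raises(ConfigurationError, match="Nyquist"):
            bandpass_filter(rec, PreprocConfig(band_hz=(0.1, 60.0)))


class TestExtractEpochs:
    def make_recording(self, events, n=3000):
        data = np.arange(n, dtype=float)[:, None] * np.ones((1, 2))
        return ContinuousRecording(data, 250.0, ["Pz", "Cz"], events=events)

    def test_window_index_arithmetic_at_250hz(self):
        rec = self.make_recording([EventMarker(1000, "target")])
        es = extract_epochs(rec)
        np.testing.assert_array_equal(es.epochs[0, :, 0], np.arange(1000, 1250))
        np.testing.assert_array_equal(es.baseline[0, :, 0], np.arange(975, 1000))
        assert es.labels[0] == 1

    def test_one_epoch_per_valid_event(self):
        rec = self.make_recording([EventMarker(500, "target"),
                                   EventMarker(1500, "nontarget")])
        es = extract_epochs(rec)
        assert es.n_epochs == 2
        np.testing.assert_array_equal(es.labels, [1, 0])

    def test_event_near_edge_dropped_with_warning(self):
        rec = self.make_recording([EventMarker(3, "target"),
                                   EventMarker(1000, "nontarget")])
        with pytest.warns(UserWarning, match="dropping event"):
            es = extract_epochs(rec)
        assert es.n_epochs == 1

    def test_no_events_is_contract_error(self):
        rec = self.make_recording([])
        with pytest.raises(ContractError, match="events"):
            extract_epochs(rec)


class TestBaselineCorrect:
    def make_epochs(self, epochs, baseline):
        return EpochSet(epochs=epochs, baseline=baseline,
                        times_ms=np.arange(epochs.shape[1]) * 4.0,
                        sampling_rate=250.0,
                        channel_names=[f"c{i}" for i in range(epochs.shape[2])])

    def test_constant_epoch_becomes_zero(self):
        es = self.make_epochs(np.full((2, 10, 3), 5.0), np.full((2, 4, 3), 5.0))
        out = baseline_correct(es)
        np.testing.assert_allclose(out.epochs, 0.0)
        assert out.baseline is None

    def test_per_channel_offsets_subtracted(self):
        epochs = np.zeros((1, 6, 2))
        baseline = np.zeros((1, 4, 2))
        baseline[0, :, 0] = 2.0
        baseline[0, :, 1] = -3.0
        out = baseline_correct(self.make_epochs(epochs, baseline))
        np.testing.assert_allclose(out.epochs[0, :, 0], -2.0)
        np.testing.assert_allclose(out.epochs[0, :, 1], 3.0)

    def test_zero_mean_baseline_leaves_epochs_unchanged(self, rng):
        epochs = rng.normal(size=(3, 8, 2))
        baseline = np.stack([np.linspace(-1, 1, 4)] * 2, axis=1)[None].repeat(3, 0)
        baseline -= baseline.mean(axis=1, keepdims=True)
        out = baseline_correct(self.make_epochs(epochs, baseline))
        np.testing.assert_allclose(out.epochs, epochs, atol=1e-12)

    def test_missing_baseline_is_contract_error(self):
        es = self.make_epochs(np.zeros((1, 6, 1)), np.zeros((1, 2, 1)))
        es.baseline = None
        with pytest.raises(ContractError, match="baseline"):
            baseline_correct(es)

    def test_baseline_mean_is_numerically_zero_after_correction(self, rng):
        epochs = rng.normal(size=(20, 250, 10))
        baseline = rng.normal(size=(20, 25, 10))
        es = self.make_epochs(epochs, baseline)
        corrected = (baseline - baseline.mean(axis=1, keepdims=True))
        out = baseline_correct(es)
        # applying the same offsets to the stored baseline zeroes its mean
        assert np.abs(corrected.mean(axis=1)).max() <= 1e-9
        np.testing.assert_allclose(
            out.epochs, epochs - baseline.mean(axis=1, keepdims=True))


class TestResample:
    def make_epochs(self, data, fs=250.0, n_ch=None):
        n_ch = data.shape[2]
        return EpochSet(epochs=data, times_ms=np.arange(data.shape[1]) / fs * 1000.0,
                        sampling_rate=fs,
                        channel_names=[f"c{i}" for i in range(n_ch)])

    def test_250_to_150_points_channels_unchanged(self, rng):
        es = self.make_epochs(rng.normal(size=(4, 250, 10)))
        out = resample_epochs(es, 150)
        assert out.epochs.shape == (4, 150, 10)
        assert out.times_ms.shape == (150,)
        assert out.sampling_rate == pytest.approx(150.0)

    def test_constant_epoch_stays_constant(self):
        es = self.make_epochs(np.full((2, 250, 3), 7.5))
        out = resample_epochs(es, 150)
        np.testing.assert_allclose(out.epochs, 7.5, atol=1e-6)

    def test_band_limited_sine_matches_continuous_form(self):
        fs = 250.0
        t = np.arange(250) / fs
        sine = np.sin(2 * np.pi * 5.0 * t)
        es = self.make_epochs(sine[None, :, None])
        out = resample_epochs(es, 150)
        expected = np.sin(2 * np.pi * 5.0 * out.times_ms / 1000.0)
        inner = slice(5, -5)  # edges carry residual filter transients
        assert np.abs(out.epochs[0, inner, 0] - expected[inner]).max() < 0.01

    def test_preserves_epoch_mean_of_band_limited_signal(self):
        fs = 250.0
        t = np.arange(250) / fs
        sig = 2.0 + np.sin(2 * np.pi * 5.0 * t)
        es = self.make_epochs(sig[None, :, None])
        out = resample_epochs(es, 150)
        assert out.epochs[0, :, 0].mean() == pytest.approx(
            es.epochs[0, :, 0].mean(), rel=0.01)

    def test_strict_montage_rejects_wrong_channel_count(self, rng):
        es = self.make_epochs(rng.normal(size=(1, 250, 3)))
        with pytest.raises(MontageError):
            resample_epochs(es, 150, strict_montage=True)


class TestPipeline:
    def test_full_pipeline_is_deterministic(self, rng):
        data = rng.normal(size=(4000, 10))
        from p300adapt.containers import CANONICAL_MONTAGE

        rec = ContinuousRecording(data, 250.0, list(CANONICAL_MONTAGE),
                                  events=[EventMarker(500, "target"),
                                          EventMarker(2000, "nontarget")])
        a = preprocess_recording(rec)
        b = preprocess_recording(rec)
        np.testing.assert_array_equal(a.epochs, b.epochs)
        assert a.epochs.shape == (2, 150, 10)
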