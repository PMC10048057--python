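"""Unit tests for the preprocessing chain."""

import numpy as np
import pytest

from forcemi.containers import RawRecording
from forcemi.preprocess import (car, downsample, drop_eog, epoch, filter_chain,
                                mi_bandpass, normalize, preprocess_recording,
                                rereference_mastoid)


def _rec(signals, fs=1000.0, labels=None, events=()):
    labels = labels or [f"ch{i}" for i in range(len(signals))]
    return RawRecording(np.asarray(signals, dtype=float), fs, labels,
                        np.asarray(events, dtype=np.int64).reshape(-1, 2))


def _tone(freq, fs=1000.0, dur=10.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestMastoidReference:
    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 500))
        rec = _rec(x, labels=["a", "b", "M1", "M2"])
        out = rereference_mastoid(rec)
        expected = x - (x[2] + x[3]) / 2.0
        np.testing.assert_allclose(out.signals, expected)

    def test_common_signal_zeroed_and_zero_mastoids_identity(self):
        common = _rec(np.ones((3, 100)), labels=["a", "M1", "M2"])
        assert np.allclose(rereference_mastoid(common).signals, 0)
        x = np.vstack([np.arange(100.0)[None], np.zeros((2, 100))])
        rec = _rec(x, labels=["a", "M1", "M2"])
        np.testing.assert_allclose(rereference_mastoid(rec).signals, x)

    def test_missing_mastoid_raises(self):
        rec = _rec(np.zeros((2, 10)), labels=["a", "M1"])
        with pytest.raises(KeyError, match="M2"):
            rereference_mastoid(rec)


class TestFilterChain:
    def test_50hz_attenuated_10hz_preserved_dc_removed(self):
        sl = slice(2000, -2000)  # avoid convolution edge transients
        out50 = filter_chain(_rec([_tone(50.0)])).signals[0]
        assert np.sqrt(np.mean(out50[sl] ** 2)) / np.sqrt(0.5) <= 0.1
        out10 = filter_chain(_rec([_tone(10.0)])).signals[0]
        assert abs(np.sqrt(np.mean(out10[sl] ** 2)) / np.sqrt(0.5) - 1) < 0.1
        outdc = filter_chain(_rec([np.full(10000, 7.0)])).signals[0]
        assert np.mean(np.abs(outdc[sl])) < 0.07  # <1% of the 7 uV offset

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            filter_chain(_rec([np.zeros(1000)], fs=150.0))


class TestCAR:
    def test_included_mean_conserved_at_zero(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.standard_normal((6, 200)))
        out = car(rec)
        np.testing.assert_allclose(out.signals.mean(axis=0), 0, atol=1e-12)

    def test_single_nonzero_channel_scaled(self):
        k = 5
        x = np.zeros((k, 50))
        x[0] = 1.0
        out = car(_rec(x))
        np.testing.assert_allclose(out.signals[0], (k - 1) / k)

    def test_identical_channels_zeroed_and_excluded_untouched(self):
        x = np.ones((4, 30))
        rec = _rec(x, labels=["a", "b", "c", "HEOG"])
        out = car(rec, exclude=("HEOG",))
        np.testing.assert_allclose(out.signals[:3], 0, atol=1e-15)
        np.testing.assert_allclose(out.signals[3], 1.0)

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError):
            car(_rec(np.zeros((2, 10))), exclude=("ch0", "ch1"))


class TestMiBandpass:
    @pytest.mark.parametrize("freq,kind", [(4.0, "stop"), (45.0, "stop"),
                                           (15.0, "pass")])
    def test_band_edges(self, freq, kind):
        out = mi_bandpass(_rec([_tone(freq)])).signals[0][2000:-2000]
        ratio = np.sqrt(np.mean(out ** 2)) / np.sqrt(0.5)
        if kind == "stop":
            assert ratio <= 0.1
        else:
            assert abs(ratio - 1) < 0.1


class TestDownsample:
    def test_length_and_event_rescaling(self):
        rec = _rec([np.zeros(10000)], events=[(6000, 1)])
        out = downsample(rec, 128.0)
        assert out.signals.shape[1] == 1280
        assert out.fs == 128.0
        assert out.events[0, 0] == 768

    def test_spectral_peak_preserved(self):
        out = downsample(_rec([_tone(15.0)]), 128.0).signals[0]
        spec = np.abs(np.fft.rfft(out))
        freqs = np.fft.rfftfreq(len(out), 1 / 128.0)
        assert abs(freqs[np.argmax(spec)] - 15.0) < 0.2

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            downsample(_rec([np.zeros(100)], fs=100.0), 128.0)


class TestDropEog:
    def test_removes_eog_and_preserves_order(self):
        labels = ["FP1", "HEOG", "C3", "VEOG", "O1"]
        rec = _rec(np.arange(5)[:, None] * np.ones((5, 10)), labels=labels)
        out = drop_eog(rec)
        assert out.channel_labels == ["FP1", "C3", "O1"]
        np.testing.assert_allclose(out.signals[:, 0], [0, 2, 4])

    def test_noop_with_warning_when_absent(self):
        rec = _rec(np.zeros((2, 10)), labels=["C3", "C4"])
        with pytest.warns(UserWarning, match="no EOG"):
            out = drop_eog(rec)
        assert out.channel_labels == ["C3", "C4"]


class TestEpoch:
    def test_window_lengths(self):
        rec = _rec([np.zeros(128 * 20)], fs=128.0, events=[(128 * 8, 0)])
        assert epoch(rec, (0, 6)).n_times == 768
        assert epoch(rec, (-1, 6)).n_times == 896

    def test_out_of_bounds_names_trial(self):
        rec = _rec([np.zeros(100)], fs=10.0, events=[(95, 0)])
        with pytest.raises(ValueError, match="trial 0"):
            epoch(rec, (0, 2))


class TestNormalize:
    def test_mean_zero_std_one_and_affine_invariance(self, tiny_session,
                                                     suppress_mastoid_warning):
        trials = preprocess_recording(tiny_session, window=(0.0, 1.0),
                                      do_normalize=False)
        out = normalize(trials)
        flat = out.data.reshape(out.n_trials, -1)
        np.testing.assert_allclose(flat.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(flat.std(axis=1), 1, atol=1e-6)
        scaled = trials
        scaled.data = trials.data * 3.0 + 11.0
        np.testing.assert_allclose(normalize(scaled).data, out.data,
                                   atol=1e-9)

    def test_hand_computed_example(self):
        from forcemi.containers import TrialSet
        ts = TrialSet(np.array([[[1.0, 2.0], [3.0, 4.0]]]), [0], 1.0,
                      (0, 2), ["a", "b"])
        out = normalize(ts).data[0]
        np.testing.assert_allclose(
            out, [[-1.342, -0.447], [0.447, 1.342]], atol=1e-3)

    def test_zero_variance_rejected(self):
        from forcemi.containers import TrialSet
        ts = TrialSet(np.ones((1, 2, 4)), [0], 1.0, (0, 4), ["a", "b"])
        with pytest.raises(ValueError, match="zero variance"):
            normalize(ts)


class TestFullChain:
    def test_band_power_dominant_and_finite(self, tiny_session,
                                            suppress_mastoid_warning):
        trials = preprocess_recording(tiny_session, window=(0.0, 6.0),
                                      do_normalize=False)
        assert trials.data.shape == (12, 30, 768)
        assert np.all(np.isfinite(trials.data))
        spec = np.abs(np.fft.rfft(trials.data, axis=2)) ** 2
        freqs = np.fft.rfftfreq(trials.n_times, 1 / trials.fs)
        inband = (freqs >= 7.0) & (freqs <= 31.0)
        frac = spec[:, :, inband].sum() / spec.sum()
        assert frac >= 0.9

    def test_trial_permutation_commutes(self, tiny_session,
                                        suppress_mastoid_warning):
        trials = preprocess_recording(tiny_session, window=(0.0, 1.0))
        perm = np.random.default_rng(3).permutation(trials.n_trials)
        from forcemi.containers import TrialSet
        permuted = TrialSet(trials.data[perm], trials.labels[perm], trials.fs,
                            trials.window, trials.channel_labels)
        renorm = normalize(permuted)
        np.testing.assert_allclose(renorm.data, trials.data[perm], atol=1e-9)
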