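"""Filtering, artifact rejection, epoching, trial matching, sensor selection."""

import numpy as np
import pytest

from segtag.preprocess import (bandpass, bandstop_line, detect_artifacts,
                               epoch_and_downsample, match_trial_counts,
                               reject_range, select_m100_sensors)
from segtag.simulate import TrialDataset

FS = 1200.0
N = round(11.7 * FS)
T = np.arange(N) / FS


def _sine(f):
    return np.sin(2 * np.pi * f * T)[None, None, :]


class TestFilters:
    def test_bandpass_attenuates_slow_drift(self):
        out = bandpass(_sine(0.1), FS, 1.0, 160.0)
        mid = slice(N // 4, 3 * N // 4)
        atten = np.abs(out[0, 0, mid]).max() / 1.0
        assert atten < 0.1  # > 20 dB

    def test_bandpass_preserves_in_band_tone(self):
        out = bandpass(_sine(10.0), FS, 1.0, 160.0)
        mid = slice(N // 4, 3 * N // 4)
        assert np.abs(out[0, 0, mid]).max() == pytest.approx(1.0, rel=0.01)

    def test_bandpass_is_zero_phase(self):
        x = _sine(10.0)[0, 0]
        y = bandpass(x[None, None], FS, 1.0, 160.0)[0, 0]
        xc = np.correlate(y[2000:-2000], x[2000:-2000], mode="full")
        assert np.argmax(xc) == len(y[2000:-2000]) - 1  # zero lag

    def test_zero_input_zero_output(self):
        assert np.allclose(bandpass(np.zeros((1, 1, N)), FS, 1, 160), 0)
        assert np.allclose(bandstop_line(np.zeros((1, 1, N)), FS), 0)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(_sine(10), 300.0, 1.0, 160.0)

    def test_bandstop_notches_line_noise_only(self):
        mid = slice(N // 4, 3 * N // 4)
        out50 = bandstop_line(_sine(50.0), FS)
        assert np.abs(out50[0, 0, mid]).max() < 0.1
        out45 = bandstop_line(_sine(45.0), FS)
        assert np.abs(out45[0, 0, mid]).max() == pytest.approx(1.0, rel=0.05)


class TestArtifactDetection:
    def test_muscular_burst_flagged_exactly(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((20, 6, N))
        data[7] += 50 * np.sin(2 * np.pi * 120 * T) * ((T > 3) & (T < 3.2))
        rep = detect_artifacts(data, FS, "muscular")
        assert list(rep.rejected["muscular"]) == [7]
        assert rep.thresholds["muscular"] == 15.0

    def test_step_discontinuity_flagged_as_jump(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((20, 6, N))
        data[3, :, 5000:] += 30.0
        rep = detect_artifacts(data, FS, "jump")
        assert list(rep.rejected["jump"]) == [3]

    def test_clean_gaussian_data_not_rejected(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((100, 6, N // 4))
        for kind in ("muscular", "jump"):
            rep = detect_artifacts(data, FS, kind)
            assert rep.rejected[kind].size == 0

    def test_rejection_is_idempotent(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((20, 6, N // 4))
        data[5] += 40 * np.sin(2 * np.pi * 125 * T[:N // 4]) * (T[:N // 4] < 0.5)
        rep = detect_artifacts(data, FS, "muscular")
        clean = np.delete(data, rep.rejected["muscular"], axis=0)
        rep2 = detect_artifacts(clean, FS, "muscular")
        assert rep2.rejected["muscular"].size == 0

    def test_zero_variance_sensor_warns(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((5, 3, N // 4))
        data[:, 1] = 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            detect_artifacts(data, FS, "muscular")

    def test_low_sample_rate_rejected_for_muscular(self):
        with pytest.raises(ValueError):
            detect_artifacts(np.zeros((2, 2, 100)), 200.0, "muscular")


class TestRangeRejection:
    def test_constant_channels_never_rejected(self):
        rep = reject_range(np.ones((5, 3, 100)))
        assert rep.rejected["range"].size == 0

    def test_drift_beyond_threshold_rejected(self):
        data = np.zeros((3, 2, 100))
        data[1, 0] = np.linspace(0, 1e-5, 100)
        rep = reject_range(data, threshold=0.75e-5)
        assert list(rep.rejected["range"]) == [1]

    def test_infinite_threshold_rejects_nothing(self):
        rng = np.random.default_rng(0)
        rep = reject_range(rng.standard_normal((10, 4, 100)), threshold=np.inf)
        assert rep.rejected["range"].size == 0


class TestEpochAndDownsample:
    def _dataset(self, n_trials=2):
        rng = np.random.default_rng(0)
        return TrialDataset(rng.standard_normal((n_trials, 3, N)),
                            np.abs(rng.standard_normal((n_trials, N))),
                            np.array(["a"] * n_trials), FS, -2.1)

    def test_sample_count_matches_window_times_rate(self):
        out = epoch_and_downsample(self._dataset(), (-2.1, 9.6), 500.0)
        assert out.n_samples == 5850  # 11.7 s x 500 Hz
        assert out.envelope.shape[1] == 5850
        assert out.fs_hz == 500.0

    def test_tagged_tone_amplitude_preserved(self):
        x = np.sin(2 * np.pi * 4.0 * T)
        ds = TrialDataset(np.tile(x, (1, 2, 1)), np.abs(x)[None], np.array(["a"]),
                          FS, -2.1)
        out = epoch_and_downsample(ds, (-2.1, 9.6), 500.0)
        mid = slice(500, -500)
        assert np.abs(out.data[0, 0, mid]).max() == pytest.approx(1.0, rel=0.01)

    def test_spectrum_at_4hz_survives_downsampling(self):
        from segtag.spectral import evoked_spectrum

        rng = np.random.default_rng(1)
        x = np.sin(2 * np.pi * 4.0 * T) + 0.1 * rng.standard_normal(N)
        ds = TrialDataset(np.tile(x, (1, 1, 1)), np.abs(x)[None], np.array(["a"]),
                          FS, -2.1)
        hi = evoked_spectrum(ds.data, FS, -2.1)
        lo_ds = epoch_and_downsample(ds, (-2.1, 9.6), 400.0)
        lo = evoked_spectrum(lo_ds.data, 400.0, -2.1)
        p_hi = hi.values[0, hi.bin_index(4.0)]
        p_lo = lo.values[0, lo.bin_index(4.0)]
        assert p_lo == pytest.approx(p_hi, rel=0.01)

    def test_window_outside_epoch_raises(self):
        with pytest.raises(ValueError):
            epoch_and_downsample(self._dataset(), (-3.0, 9.6), 500.0)


class TestMatchTrialCounts:
    def _dataset(self, counts, correct=None):
        n = sum(counts.values())
        conds = np.concatenate([[c] * k for c, k in counts.items()])
        rng = np.random.default_rng(0)
        return TrialDataset(rng.standard_normal((n, 2, 50)),
                            np.abs(rng.standard_normal((n, 50))), conds, 500.0,
                            0.0, correct_response=correct)

    def test_counts_equalized_to_minimum(self):
        ds = match_trial_counts(self._dataset({"a": 70, "b": 65}), seed=0)
        conds = list(ds.condition)
        assert conds.count("a") == 65 and conds.count("b") == 65

    def test_equal_counts_keep_everything(self):
        ds = match_trial_counts(self._dataset({"a": 10, "b": 10}), seed=0)
        assert ds.n_trials == 20

    def test_incorrect_trials_dropped_first(self):
        correct = np.ones(20, bool)
        correct[:4] = False  # four incorrect 'a' trials
        ds = match_trial_counts(self._dataset({"a": 10, "b": 10}, correct), seed=0)
        conds = list(ds.condition)
        assert conds.count("a") == 6 and conds.count("b") == 6

    def test_seeded_selection_is_reproducible(self):
        base = self._dataset({"a": 30, "b": 20})
        a = match_trial_counts(base, seed=3)
        b = match_trial_counts(base, seed=3)
        assert np.array_equal(a.data, b.data)


class TestM100Selection:
    def test_dipolar_evoked_selects_high_gain_sensors(self, fwd):
        rng = np.random.default_rng(0)
        j = 40
        from segtag.simulate import SimulationConfig, _source_orientations

        ori = _source_orientations(fwd, SimulationConfig(effect_2hz={}), rng)[j]
        gain = fwd.leadfield_for(j) @ ori
        fs, dur = 600.0, 0.4
        t = np.arange(round(dur * fs)) / fs
        m100 = np.exp(-0.5 * ((t - 0.1) / 0.02) ** 2)
        evoked = np.outer(gain, m100) + 0.01 * rng.standard_normal((fwd.n_sensors, t.size))
        sel = select_m100_sensors(evoked, fs, k=8)
        top_gain = set(np.argsort(-np.abs(gain))[:8].tolist())
        assert len(set(sel.tolist()) & top_gain) >= 6

    def test_k_equal_n_sensors_returns_all(self):
        evoked = np.random.default_rng(0).standard_normal((5, 100))
        assert list(select_m100_sensors(evoked, 500.0, k=5)) == [0, 1, 2, 3, 4]

    def test_flat_evoked_breaks_ties_by_index(self):
        sel = select_m100_sensors(np.ones((6, 100)), 500.0, k=3)
        assert list(sel) == [0, 1, 2]

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            select_m100_sensors(np.ones((4, 100)), 500.0, k=5)
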