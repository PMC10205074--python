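"""Filtering, artifact rejection, epoching/downsampling, trial matching.

The chain mirrors a standard MEG pipeline: zero-phase Butterworth band-pass
(1-160 Hz, order 4), line-noise band-stops (50/100/150 Hz +- 0.5 Hz),
z-score based rejection of muscular (band 110-140 Hz, z > 15) and jump
(median-filter residual, z > 30) artifacts, per-channel range rejection,
anti-aliased downsampling to 500 Hz with epoching at (-2.1, 9.6) s, and
seeded matching of trial counts across conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .simulate import TrialDataset

__all__ = ["ArtifactReport", "bandpass", "bandstop_line", "detect_artifacts",
           "reject_range", "epoch_and_downsample", "match_trial_counts",
           "select_m100_sensors"]


@dataclass
class ArtifactReport:
    trial_z: np.ndarray                 # per-trial max sensor-averaged z
    rejected: dict[str, np.ndarray]     # criterion -> trial indices
    thresholds: dict[str, float]

    def rejected_any(self) -> np.ndarray:
        if not self.rejected:
            return np.array([], int)
        return np.unique(np.concatenate(list(self.rejected.values())))


def _sos_filtfilt(sos: np.ndarray, data: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, data, axis=-1)


def bandpass(data: np.ndarray, fs_hz: float, low_hz: float, high_hz: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase (forward-reverse) Butterworth band-pass along time."""
    nyq = fs_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz outside (0, {nyq}) Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs_hz,
                        output="sos")
    return _sos_filtfilt(sos, np.asarray(data, float))


def bandstop_line(data: np.ndarray, fs_hz: float,
                  centers_hz: tuple[float, ...] = (50.0, 100.0, 150.0),
                  half_width_hz: float = 0.5, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-stops at the line frequency and harmonics.

    Centers at or above Nyquist are skipped.
    """
    out = np.asarray(data, float)
    nyq = fs_hz / 2.0
    for c in centers_hz:
        if c + half_width_hz >= nyq:
            continue
        sos = signal.butter(order, [c - half_width_hz, c + half_width_hz],
                            btype="bandstop", fs=fs_hz, output="sos")
        out = _sos_filtfilt(sos, out)
    return out


def _zscore_per_sensor(x: np.ndarray, pooled: bool) -> np.ndarray:
    """z over time, per sensor; optionally pooling statistics across trials."""
    if pooled:
        mu = x.mean(axis=(0, 2), keepdims=True)
        sd = x.std(axis=(0, 2), keepdims=True)
    else:
        mu = x.mean(axis=2, keepdims=True)
        sd = x.std(axis=2, keepdims=True)
    bad = sd == 0
    if np.any(bad):
        warnings.warn("zero-variance sensor(s) excluded from artifact z-scoring")
        sd = np.where(bad, 1.0, sd)
    z = (x - mu) / sd
    return np.where(bad, np.nan, z)


def detect_artifacts(data: np.ndarray, fs_hz: float, kind: str,
                     z_threshold: float | None = None,
                     median_window: int = 9,
                     pooled_stats: bool = True) -> ArtifactReport:
    """Flag trials whose sensor-averaged artifact z-score exceeds threshold.

    ``muscular``: band-pass 110-140 Hz, amplitude envelope, z per sensor
    (default z = 15).  ``jump``: residual of a running-median filter
    (default window 9 samples), z per sensor (default z = 30).  z-scores
    are averaged across sensors to accumulate evidence over sensors, and
    the per-trial maximum is compared to the threshold.

    z statistics are pooled over the whole trial set per sensor (the
    standard choice): normalizing each trial by its own statistics would
    let a large artifact inflate its own denominator and cap the
    attainable z below the rejection thresholds.  ``pooled_stats=False``
    selects the per-trial variant.
    """
    data = np.asarray(data, float)
    if data.ndim != 3:
        raise ValueError("expected (trials, sensors, samples)")
    if kind == "muscular":
        if fs_hz <= 280:
            raise ValueError("sample rate too low for the 110-140 Hz muscular band")
        thr = 15.0 if z_threshold is None else z_threshold
        filt = bandpass(data, fs_hz, 110.0, 140.0)
        mag = np.abs(signal.hilbert(filt, axis=-1))
    elif kind == "jump":
        thr = 30.0 if z_threshold is None else z_threshold
        # median filter suppresses noise spikes while preserving steps;
        # the absolute first difference then isolates discontinuities
        med = ndimage.median_filter(data, size=(1, 1, median_window),
                                    mode="nearest")
        mag = np.abs(np.diff(med, axis=-1, prepend=med[:, :, :1]))
    else:
        raise ValueError(f"unknown artifact kind: {kind!r}")

    z = _zscore_per_sensor(mag, pooled_stats)
    z_mean = np.nanmean(np.where(np.isfinite(z), z, np.nan), axis=1)  # (tr, samp)
    trial_z = z_mean.max(axis=1)
    rejected = np.flatnonzero(trial_z > thr)
    return ArtifactReport(trial_z, {kind: rejected}, {kind: thr})


def reject_range(data: np.ndarray, threshold: float = 0.75e-5) -> ArtifactReport:
    """Reject trials where any channel's min-max range exceeds threshold."""
    data = np.asarray(data, float)
    rng = np.ptp(data, axis=2)          # (trials, sensors)
    trial_stat = rng.max(axis=1)
    rejected = np.flatnonzero(trial_stat > threshold)
    return ArtifactReport(trial_stat, {"range": rejected}, {"range": threshold})


def epoch_and_downsample(dataset: TrialDataset,
                         window_s: tuple[float, float] = (-2.1, 9.6),
                         fs_out: float = 500.0) -> TrialDataset:
    """Crop to ``window_s`` and resample (anti-aliased) to ``fs_out``.

    The acoustic envelope is cropped and resampled identically.  Output
    sample count is round(window length x fs_out).
    """
    from fractions import Fraction

    t = dataset.times
    if window_s[0] < t[0] - 0.5 / dataset.fs_hz or window_s[1] > t[-1] + 1.5 / dataset.fs_hz:
        raise ValueError("requested window exceeds the epoch bounds")
    i0 = round((window_s[0] - dataset.t_start_s) * dataset.fs_hz)
    n_in = round((window_s[1] - window_s[0]) * dataset.fs_hz)
    frac = Fraction(fs_out / dataset.fs_hz).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = dataset.data[:, :, i0:i0 + n_in]
    env = dataset.envelope[:, i0:i0 + n_in]
    if (up, down) != (1, 1):
        data = signal.resample_poly(data, up, down, axis=-1)
        env = signal.resample_poly(env, up, down, axis=-1)
    n_out = round((window_s[1] - window_s[0]) * fs_out)
    data, env = data[:, :, :n_out], env[:, :n_out]
    return TrialDataset(np.ascontiguousarray(data), np.ascontiguousarray(env),
                        dataset.condition, fs_out, window_s[0],
                        dataset.correct_response, dataset.block_index,
                        dataset.ground_truth)


def match_trial_counts(dataset: TrialDataset, seed: int = 0) -> TrialDataset:
    """Equalize correct-response trial counts across conditions.

    Keeps only correct-response trials, then randomly subsamples every
    condition down to the smallest per-condition count (seeded).
    """
    rng = np.random.default_rng(seed)
    correct = np.flatnonzero(dataset.correct_response)
    conds = np.asarray(dataset.condition)[correct]
    uniq, counts = np.unique(conds, return_counts=True)
    n_min = counts.min()
    keep: list[int] = []
    for c in uniq:
        idx = correct[conds == c]
        keep.extend(rng.choice(idx, size=n_min, replace=False))
    return dataset.select(np.sort(keep))


def select_m100_sensors(evoked: np.ndarray, fs_hz: float, k: int,
                        latency_window_s: tuple[float, float] = (0.08, 0.12),
                        t_start_s: float = 0.0) -> np.ndarray:
    """Auditory (M100) sensor selection from a tone-localizer evoked response.

    Returns the ``k`` sensors with largest RMS amplitude in the latency
    window after tone onset; ties break toward the lower sensor index.
    """
    evoked = np.asarray(evoked, float)
    if k > evoked.shape[0]:
        raise ValueError("k exceeds the number of sensors")
    i0 = round((latency_window_s[0] - t_start_s) * fs_hz)
    i1 = round((latency_window_s[1] - t_start_s) * fs_hz)
    rms = np.sqrt(np.mean(evoked[:, i0:i1] ** 2, axis=1))
    order = np.argsort(-rms, kind="stable")
    return np.sort(order[:k])
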