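"""Simulated multichannel trial data with known ground truth.

Each trial mixes three components through the toy leadfield:

* a 4 Hz auditory response in the auditory ROIs, phase-locked to the
  trial's acoustic envelope (enabling cerebro-acoustic coherence), with a
  slow random amplitude fluctuation;
* a 2 Hz response in condition-dependent ROIs, phase-locked to unit
  onsets; when ``cfc_strength`` > 0 its instantaneous amplitude follows
  the standardized 4 Hz amplitude fluctuation (cross-frequency coupling);
* spatially correlated 1/f^a background noise scaled by the
  signal-to-noise ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .forward import ToyForwardModel
from .lexicon import StimulusSequence

__all__ = ["SimulationConfig", "TrialDataset", "syllable_envelope",
           "one_over_f_noise", "simulate_trials"]


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the simulated experiment."""

    fs_hz: float = 1200.0
    epoch_window_s: tuple[float, float] = (-2.1, 9.6)
    syllable_rate_hz: float = 4.0
    unit_rate_hz: float = 2.0
    snr: float = 5.0
    effect_2hz: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    effect_4hz: float = 1.0
    cfc_strength: float = 0.0
    noise_exponent: float = 1.0
    amplitude_mod_hz: float = 0.3   # bandwidth of the slow 4 Hz amplitude fluctuation
    orientation: str = "dominant"   # "dominant" (max leadfield gain) or "random"
    p_correct: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        if not 0.0 <= self.cfc_strength <= 1.0:
            raise ValueError("cfc_strength must be in [0, 1]")
        if abs(self.unit_rate_hz - self.syllable_rate_hz / 2) > 1e-12:
            raise ValueError("unit rate must be half the syllable rate")
        if self.epoch_window_s[1] <= self.epoch_window_s[0]:
            raise ValueError("epoch window must be non-empty")


@dataclass
class TrialDataset:
    """Trials x sensors x samples data with aligned acoustic envelopes."""

    data: np.ndarray                # (n_trials, n_sensors, n_samples)
    envelope: np.ndarray            # (n_trials, n_samples)
    condition: np.ndarray           # (n_trials,) str
    fs_hz: float
    t_start_s: float
    correct_response: np.ndarray | None = None
    block_index: np.ndarray | None = None
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if self.data.shape[0] != self.envelope.shape[0]:
            raise ValueError("data and envelope must share the trial count")
        if self.data.shape[2] != self.envelope.shape[1]:
            raise ValueError("data and envelope must share the sample count")
        if not (np.all(np.isfinite(self.data)) and np.all(np.isfinite(self.envelope))):
            raise ValueError("data and envelope must be finite")
        if self.correct_response is None:
            self.correct_response = np.ones(self.n_trials, bool)
        if self.block_index is None:
            self.block_index = np.zeros(self.n_trials, int)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t_start_s + np.arange(self.n_samples) / self.fs_hz

    def select(self, idx: np.ndarray) -> "TrialDataset":
        idx = np.asarray(idx)
        return TrialDataset(self.data[idx], self.envelope[idx],
                            np.asarray(self.condition)[idx], self.fs_hz,
                            self.t_start_s, self.correct_response[idx],
                            self.block_index[idx], self.ground_truth)


def syllable_envelope(sequence: StimulusSequence, fs_hz: float,
                      window_s: tuple[float, float]) -> np.ndarray:
    """Model acoustic amplitude envelope: one smooth bump per syllable.

    Each token contributes a Hann bump over its content duration (plosive
    tokens start 20 ms late), so the envelope is periodic at the syllable
    rate with no energy at the unit rate.  Zero outside the stimulus.
    """
    n = round((window_s[1] - window_s[0]) * fs_hz)
    env = np.zeros(n)
    for onset, tok in zip(sequence.onsets_s, sequence.tokens):
        t0 = onset + tok.silence_before_s - window_s[0]
        i0 = round(t0 * fs_hz)
        m = round(tok.content_duration_s * fs_hz)
        bump = np.hanning(m)
        sl = slice(max(i0, 0), min(i0 + m, n))
        env[sl] += bump[sl.start - i0: sl.stop - i0]
    return env


def one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                     exponent: float, fs_hz: float) -> np.ndarray:
    """Independent 1/f^exponent noise channels, unit variance each."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs_hz)
    gain = np.ones_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    gain[0] = 0.0
    white = rng.standard_normal((n_channels, n_samples))
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * gain, n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _slow_modulator(rng: np.random.Generator, n: int, fs: float,
                    cutoff_hz: float) -> np.ndarray:
    """Standardized low-pass random fluctuation, clipped to +-1."""
    raw = one_over_f_noise(rng, 1, n, 0.0, fs)[0]
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    slow = signal.sosfiltfilt(sos, raw)
    sd = slow.std()
    if sd == 0:
        return np.zeros(n)
    return np.clip(slow / sd, -1.0, 1.0)


def _source_signals(forward: ToyForwardModel, config: SimulationConfig,
                    sequences: Sequence[StimulusSequence],
                    rng: np.random.Generator):
    """Per-trial source-space signals of the generative model.

    Yields (trial index, (n_active_sources,) indices, signals array,
    envelope); also returns shared ground-truth arrays via the closure
    attributes set on the generator object by the caller.
    """
    fs = config.fs_hz
    t0, t1 = config.epoch_window_s
    n_samp = round((t1 - t0) * fs)
    times = t0 + np.arange(n_samp) / fs

    aud_idx = np.concatenate([forward.roi_labels["auditory_left"],
                              forward.roi_labels["auditory_right"]])
    # fixed per-source phase offsets for both tagged responses: neighboring
    # neural populations respond with similar but not identical timing, and
    # fully coherent extended patches would be cancelled by beamformers.
    # The spread (a third of a cycle) models tens of ms of timing jitter;
    # a constant offset leaves the coherence magnitude with the envelope
    # unchanged.
    phase_2hz = rng.uniform(0.0, 2.0 * np.pi / 3.0, forward.n_sources)
    phase_4hz = rng.uniform(0.0, 2.0 * np.pi / 3.0, forward.n_sources)
    sos4 = signal.butter(4, [config.syllable_rate_hz - 1.0,
                             config.syllable_rate_hz + 1.0],
                         btype="bandpass", fs=fs, output="sos")

    for seq in sequences:
        env = syllable_envelope(seq, fs, (t0, t1))
        stim = (times >= 0) & (times <= seq.duration_s)
        mod = _slow_modulator(rng, n_samp, fs, config.amplitude_mod_hz)
        # auditory drive: syllable-rate band of the acoustic envelope, so
        # the 4 Hz response is phase-locked to the envelope without
        # spilling energy into the unit-rate (2 Hz) band
        drive = signal.sosfiltfilt(sos4, env) * stim
        drive_analytic = signal.hilbert(drive)
        amp4 = config.effect_4hz * (1.0 + 0.9 * mod)
        amp2 = 1.0 + config.cfc_strength * 0.9 * mod

        src_amp = np.zeros(forward.n_sources)
        for roi, amp in config.effect_2hz[seq.condition].items():
            src_amp[forward.roi_labels[roi]] = amp
        active2 = np.flatnonzero(src_amp)

        src = np.zeros((forward.n_sources, n_samp))
        if config.effect_4hz != 0:
            for j in aud_idx:
                src[j] += amp4 * np.real(drive_analytic
                                         * np.exp(1j * phase_4hz[j]))
        for j in active2:
            src[j] += src_amp[j] * amp2 * np.sin(
                2 * np.pi * config.unit_rate_hz * times + phase_2hz[j]) * stim
        yield src, env, active2


def _source_orientations(forward: ToyForwardModel, config: SimulationConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Dipole orientation per source: dominant leadfield direction by
    default (the most magnetically visible orientation), or random."""
    if config.orientation == "random":
        ori = rng.standard_normal((forward.n_sources, 3))
        return ori / np.linalg.norm(ori, axis=1, keepdims=True)
    if config.orientation != "dominant":
        raise ValueError(f"unknown orientation mode: {config.orientation!r}")
    ori = np.empty((forward.n_sources, 3))
    for j in range(forward.n_sources):
        _, _, vt = np.linalg.svd(forward.leadfield_for(j), full_matrices=False)
        u = vt[0]
        if u[np.argmax(np.abs(u))] < 0:
            u = -u
        ori[j] = u
    return ori


def _ground_truth(forward: ToyForwardModel, config: SimulationConfig,
                  gt_2hz: dict, orientations: np.ndarray | None) -> dict:
    aud_idx = np.concatenate([forward.roi_labels["auditory_left"],
                              forward.roi_labels["auditory_right"]])
    return {
        "orientations": orientations,
        "sources_4hz": aud_idx,
        "effect_2hz": gt_2hz,
        "roi_labels": {k: np.array(v) for k, v in forward.roi_labels.items()},
        "effect_4hz": config.effect_4hz,
        "cfc_strength": config.cfc_strength,
        "snr": config.snr,
    }


def simulate_trials(forward: ToyForwardModel, config: SimulationConfig,
                    sequences: Sequence[StimulusSequence]) -> TrialDataset:
    """Simulate sensor-level trials for the given stimulus sequences."""
    if not sequences:
        raise ValueError("need at least one stimulus sequence")
    for s in sequences:
        if s.condition not in config.effect_2hz:
            raise KeyError(f"condition {s.condition!r} missing from effect_2hz")

    rng = np.random.default_rng(config.seed)
    fs = config.fs_hz
    t0, t1 = config.epoch_window_s
    n_samp = round((t1 - t0) * fs)
    n_tr = len(sequences)
    n_sens = forward.n_sensors

    # fixed dipole orientation per source (recorded in ground truth)
    orientations = _source_orientations(forward, config, rng)
    lead3 = forward.leadfield.reshape(n_sens, forward.n_sources, 3)
    lead_scalar = np.einsum("nsk,sk->ns", lead3, orientations)  # (n_sens, n_src)

    signal_part = np.zeros((n_tr, n_sens, n_samp))
    envelopes = np.zeros((n_tr, n_samp))
    gt_2hz: dict[str, dict[str, float]] = {}
    for tr, (src, env, _) in enumerate(_source_signals(forward, config,
                                                       sequences, rng)):
        envelopes[tr] = env
        signal_part[tr] = lead_scalar @ src
        gt_2hz[sequences[tr].condition] = dict(
            config.effect_2hz[sequences[tr].condition])

    s_rms = float(np.sqrt(np.mean(signal_part ** 2)))
    noise_mix = rng.standard_normal((n_sens, n_sens)) / np.sqrt(n_sens)
    data = np.empty_like(signal_part)
    noise_rms = (s_rms / config.snr) if (config.snr > 0 and s_rms > 0) else 1.0
    for tr in range(n_tr):
        g = one_over_f_noise(rng, n_sens, n_samp, config.noise_exponent, fs)
        noise = noise_mix @ g
        noise *= noise_rms / np.sqrt(np.mean(noise ** 2))
        data[tr] = (signal_part[tr] if config.snr > 0 else 0.0) + noise

    correct = rng.random(n_tr) < config.p_correct
    return TrialDataset(
        data=data, envelope=envelopes,
        condition=np.array([s.condition for s in sequences]),
        fs_hz=fs, t_start_s=t0, correct_response=correct,
        block_index=np.array([s.block_index for s in sequences]),
        ground_truth=_ground_truth(forward, config, gt_2hz, orientations))


def simulate_source_trials(forward: ToyForwardModel, config: SimulationConfig,
                           sequences: Sequence[StimulusSequence]) -> TrialDataset:
    """Simulate ground-truth source-space trials (no sensor projection).

    Channels of the returned dataset are grid sources carrying the planted
    signals plus independent 1/f noise per source at the configured
    signal-to-noise ratio; useful for testing source-level estimators
    against known truth.
    """
    if not sequences:
        raise ValueError("need at least one stimulus sequence")
    for s in sequences:
        if s.condition not in config.effect_2hz:
            raise KeyError(f"condition {s.condition!r} missing from effect_2hz")

    rng = np.random.default_rng(config.seed)
    fs = config.fs_hz
    t0, t1 = config.epoch_window_s
    n_samp = round((t1 - t0) * fs)
    n_tr = len(sequences)
    n_src = forward.n_sources

    sig = np.zeros((n_tr, n_src, n_samp))
    envelopes = np.zeros((n_tr, n_samp))
    gt_2hz: dict[str, dict[str, float]] = {}
    for tr, (src, env, _) in enumerate(_source_signals(forward, config,
                                                       sequences, rng)):
        sig[tr] = src
        envelopes[tr] = env
        gt_2hz[sequences[tr].condition] = dict(
            config.effect_2hz[sequences[tr].condition])

    s_rms = float(np.sqrt(np.mean(sig[np.abs(sig) > 0] ** 2))) if np.any(sig) else 0.0
    noise_rms = (s_rms / config.snr) if (config.snr > 0 and s_rms > 0) else 1.0
    data = np.empty_like(sig)
    for tr in range(n_tr):
        noise = one_over_f_noise(rng, n_src, n_samp, config.noise_exponent, fs)
        data[tr] = (sig[tr] if config.snr > 0 else 0.0) + noise_rms * noise

    correct = rng.random(n_tr) < config.p_correct
    return TrialDataset(
        data=data, envelope=envelopes,
        condition=np.array([s.condition for s in sequences]),
        fs_hz=fs, t_start_s=t0, correct_response=correct,
        block_index=np.array([s.block_index for s in sequences]),
        ground_truth=_ground_truth(forward, config, gt_2hz, None))
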