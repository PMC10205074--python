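"""Acoustic rendering of stimulus sequences.

Each syllable is a band-limited noise burst with a label-specific spectral
centroid under a smooth (Hann) amplitude window of the token's content
duration, peak-normalized per token; plosive-onset tokens start after
20 ms of silence.  Because the amplitude window is identical across
positions, the envelope modulation spectrum peaks at the syllable rate
with no systematic energy at the unit rate.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .lexicon import StimulusSequence

__all__ = ["synthesize_audio"]

_SILENCE_LABELS = {"", "sil", "silence"}


def _label_centroid_hz(label: str, seed: int) -> float:
    """Stable per-label spectral centroid, log-uniform in 400-3600 Hz."""
    h = np.uint64(seed & 0x7FFFFFFF)
    for ch in label:
        h = np.uint64((int(h) * 1000003 + ord(ch)) % (2 ** 31))
    u = int(h) / (2 ** 31)
    return float(400.0 * (9.0 ** u))


def synthesize_audio(sequence: StimulusSequence, fs_hz: float = 44100.0,
                     seed: int = 0) -> np.ndarray:
    """Render a sequence as a mono waveform.

    The waveform length is the number of syllables times the inter-onset
    interval at ``fs_hz``.  Labels in {"", "sil", "silence"} render as
    silence.
    """
    if fs_hz < 8000:
        raise ValueError("sample rate must be at least 8 kHz")
    rng = np.random.default_rng(seed)
    ioi = 1.0 / sequence.syllable_rate_hz
    n_total = round(len(sequence.syllables) * ioi * fs_hz)
    wave = np.zeros(n_total)
    for onset, tok in zip(sequence.onsets_s, sequence.tokens):
        if tok.label in _SILENCE_LABELS:
            continue
        n = round(tok.content_duration_s * fs_hz)
        centroid = _label_centroid_hz(tok.label, seed)
        lo = max(80.0, centroid / 1.6)
        hi = min(0.45 * fs_hz, centroid * 1.6)
        sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")
        burst = signal.sosfilt(sos, rng.standard_normal(n))
        burst *= np.hanning(n)
        peak = np.abs(burst).max()
        if peak > 0:
            burst /= peak
        i0 = round((onset + tok.silence_before_s) * fs_hz)
        sl = slice(i0, min(i0 + n, n_total))
        wave[sl] += burst[: sl.stop - sl.start]
    return wave
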