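"""Cochlear-filterbank envelopes, modulation spectra, cerebro-acoustic coherence.

The speech envelope is the across-band mean of the Hilbert magnitude of 8
zero-phase Butterworth bands spaced equidistantly on the cochlear (ERB-rate)
frequency scale between 100 and 8000 Hz, resampled to the neural sampling
rate.  Cerebro-acoustic coherence is the magnitude-squared coherence between
the envelope and beamformed source activity at the syllable rate, Fisher-z
transformed and averaged within ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .beamform import SpatialFilter, _fourier_coefficients
from .spectral import SpectrumMap

__all__ = ["EnvelopeSignal", "erb_rate", "inverse_erb_rate", "cochlear_filterbank",
           "extract_envelope", "modulation_spectrum", "cerebroacoustic_coherence"]


@dataclass
class EnvelopeSignal:
    samples: np.ndarray
    fs_hz: float
    source_trial: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.samples < 0):
            raise ValueError("envelope must be non-negative")


def erb_rate(f_hz: np.ndarray | float) -> np.ndarray:
    """ERB-rate (cochlear map) scale value of a frequency in Hz."""
    return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f_hz, float))


def inverse_erb_rate(e: np.ndarray | float) -> np.ndarray:
    return (10.0 ** (np.asarray(e, float) / 21.4) - 1.0) / 0.00437


def band_edges(n_bands: int = 8, range_hz: tuple[float, float] = (100.0, 8000.0),
               scale: str = "erb") -> np.ndarray:
    """Band edges equidistant on the chosen auditory frequency scale."""
    lo, hi = range_hz
    if scale == "erb":
        return inverse_erb_rate(np.linspace(erb_rate(lo), erb_rate(hi), n_bands + 1))
    if scale == "log":
        return np.geomspace(lo, hi, n_bands + 1)
    raise ValueError(f"unknown scale: {scale!r}")


def cochlear_filterbank(waveform: np.ndarray, fs_hz: float, n_bands: int = 8,
                        range_hz: tuple[float, float] = (100.0, 8000.0),
                        order: int = 3, scale: str = "erb") -> np.ndarray:
    """Zero-phase third-order Butterworth filterbank on the cochlear scale.

    Returns (n_bands, n_samples).
    """
    if fs_hz <= 2 * range_hz[1]:
        raise ValueError(f"sample rate {fs_hz} Hz too low for a {range_hz[1]} Hz band edge")
    edges = band_edges(n_bands, range_hz, scale)
    x = np.asarray(waveform, float)
    out = np.empty((n_bands, x.size))
    for b in range(n_bands):
        sos = signal.butter(order, [edges[b], edges[b + 1]], btype="bandpass",
                            fs=fs_hz, output="sos")
        out[b] = signal.sosfiltfilt(sos, x)
    return out


def _resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    if fs_in == fs_out:
        return x
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def extract_envelope(bands: np.ndarray, fs_in: float, fs_out: float = 500.0,
                     source_trial: int | None = None) -> EnvelopeSignal:
    """Across-band mean Hilbert magnitude, resampled to the neural rate."""
    from scipy.fft import next_fast_len

    bands = np.atleast_2d(np.asarray(bands, float))
    n = bands.shape[1]
    analytic = signal.hilbert(bands, N=next_fast_len(n), axis=1)[:, :n]
    env = np.abs(analytic).mean(axis=0)
    env = _resample(env, fs_in, fs_out)
    return EnvelopeSignal(np.clip(env, 0.0, None), fs_out, source_trial)


def modulation_spectrum(env: EnvelopeSignal | np.ndarray, fs_hz: float | None = None,
                        resolution_hz: float = 1.0 / 9.0,
                        fmax_hz: float = 20.0) -> SpectrumMap:
    """Power spectrum of the mean-removed envelope at the tagging resolution.

    Uses the first 1/resolution seconds of the envelope (zero-padding if
    shorter), so 2 Hz and 4 Hz fall exactly on bins.
    """
    if isinstance(env, EnvelopeSignal):
        x, fs = env.samples, env.fs_hz
    else:
        if fs_hz is None:
            raise ValueError("fs_hz required for a bare array")
        x, fs = np.asarray(env, float), fs_hz
    n = round(fs / resolution_hz)
    seg = x[:n] - x[:n].mean()
    if seg.size < n:
        seg = np.pad(seg, (0, n - seg.size))
    freqs, power = signal.periodogram(seg, fs=fs, window="boxcar", detrend=False)
    sel = freqs <= fmax_hz + 1e-9
    return SpectrumMap(power[None, sel], freqs[sel], kind="power", space="sensor")


def cerebroacoustic_coherence(trials: np.ndarray, envelopes: np.ndarray,
                              filt: SpatialFilter, fs_hz: float, t_start_s: float,
                              rois: dict[str, np.ndarray] | None = None,
                              target_hz: float = 4.0, taper: str = "hann",
                              analysis_window_s: tuple[float, float] = (0.5, 9.5),
                              fisher_z: bool = True) -> dict:
    """Coherence between the acoustic envelope and beamformed sources.

    Complex spectral coefficients at ``target_hz`` are computed per trial
    for all sensors and for the paired envelope; sensor coefficients are
    projected to sources through the common spatial filter (applying the
    filter to both auto- and cross-spectral terms), and magnitude-squared
    coherence across trials is formed per source.  Fisher z
    (arctanh of the magnitude coherence) is applied before ROI averaging.

    Returns a dict with per-source values (``sources``) and per-ROI means.
    """
    trials = np.asarray(trials, float)
    envelopes = np.asarray(envelopes, float)
    if trials.shape[0] != envelopes.shape[0]:
        raise ValueError("data and envelopes must have matching trial counts")

    coeff, freqs = _fourier_coefficients(trials, fs_hz, t_start_s,
                                         analysis_window_s, taper)
    k = int(np.argmin(np.abs(freqs - target_hz)))
    if abs(freqs[k] - target_hz) > 1e-6:
        raise ValueError(f"{target_hz} Hz not on the analysis grid")
    X = coeff[:, :, k]                                   # (tr, ch)

    ecoeff, _ = _fourier_coefficients(envelopes[:, None, :], fs_hz, t_start_s,
                                      analysis_window_s, taper)
    E = ecoeff[:, 0, k]                                  # (tr,)

    S = np.einsum("vc,tc->tv", filt.weights, X)          # source coefficients
    num = np.abs(np.einsum("tv,t->v", S, E.conj())) ** 2
    den = np.sum(np.abs(S) ** 2, axis=0) * np.sum(np.abs(E) ** 2)
    coh = num / den                                      # magnitude-squared, [0, 1]
    values = np.arctanh(np.clip(np.sqrt(coh), 0.0, 1.0 - 1e-12)) if fisher_z else coh

    out = {"sources": values, "coherence": coh}
    if rois is not None:
        for name, idx in rois.items():
            out[name] = float(values[idx].mean())
    return out
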