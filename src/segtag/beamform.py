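"""DICS and LCMV beamforming with common filters on the toy source grid.

DICS builds a spatial filter from a regularized sensor cross-spectral
density (CSD) matrix; LCMV is the time-domain analog built from a
band-limited covariance.  Filters use unit-gain constraints with
dominant-orientation (SVD) reduction, are computed once across conditions
(common filter), and are applied identically to each condition so that
condition contrasts are not biased by filter estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import ToyForwardModel
from .preprocess import bandpass
from .spectral import DEFAULT_OFFSETS, SpectrumMap, _taper, neighbor_bin_contrast

__all__ = ["CrossSpectralDensity", "SpatialFilter", "csd", "band_covariance",
           "dics_filter", "lcmv_filter", "source_power_contrast",
           "project_trials", "roi_average"]


@dataclass
class CrossSpectralDensity:
    matrix: np.ndarray                 # (n_sensors, n_sensors) complex Hermitian
    freq_band_hz: tuple[float, float]
    n_trials: int

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.conj().T, atol=1e-10):
            raise ValueError("CSD matrix must be Hermitian")
        d = np.real(np.diag(self.matrix))
        if np.any(d < -1e-12):
            raise ValueError("CSD diagonal must be non-negative")


@dataclass
class SpatialFilter:
    weights: np.ndarray        # (n_sources, n_sensors); complex for DICS
    lambda_frac: float
    kind: str                  # "dics" | "lcmv"
    orientations: np.ndarray   # (n_sources, 3) dominant orientation per source

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("filter weights must be finite")


def _fourier_coefficients(trials: np.ndarray, fs_hz: float, t_start_s: float,
                          analysis_window_s: tuple[float, float],
                          taper: str) -> tuple[np.ndarray, np.ndarray]:
    """Tapered FFT per trial over the analysis window.

    Returns (coefficients (n_trials, n_sensors, n_bins), freqs).
    """
    i0 = round((analysis_window_s[0] - t_start_s) * fs_hz)
    i1 = round((analysis_window_s[1] - t_start_s) * fs_hz)
    seg = np.asarray(trials, float)[:, :, i0:i1]
    n = seg.shape[2]
    w = _taper(taper, n)
    seg = (seg - seg.mean(axis=2, keepdims=True)) * w
    coeff = np.fft.rfft(seg, axis=2)
    freqs = np.fft.rfftfreq(n, 1.0 / fs_hz)
    return coeff, freqs


def csd(trials: np.ndarray, fs_hz: float, t_start_s: float,
        band_hz: tuple[float, float], taper: str = "hann",
        analysis_window_s: tuple[float, float] = (0.5, 9.5)) -> CrossSpectralDensity:
    """Sensor cross-spectral density averaged over trials and band bins."""
    coeff, freqs = _fourier_coefficients(trials, fs_hz, t_start_s,
                                         analysis_window_s, taper)
    sel = np.flatnonzero((freqs >= band_hz[0] - 1e-9) & (freqs <= band_hz[1] + 1e-9))
    if sel.size == 0:
        raise ValueError("no frequency bins inside the requested band")
    X = coeff[:, :, sel]                                    # (tr, ch, bins)
    C = np.einsum("tcb,tdb->cd", X, X.conj()) / (X.shape[0] * sel.size)
    C = 0.5 * (C + C.conj().T)
    return CrossSpectralDensity(C, tuple(band_hz), trials.shape[0])


def band_covariance(trials: np.ndarray, fs_hz: float,
                    band_hz: tuple[float, float], order: int = 4) -> np.ndarray:
    """Band-limited real sensor covariance averaged over trials."""
    filt = bandpass(np.asarray(trials, float), fs_hz, band_hz[0], band_hz[1],
                    order=order)
    filt = filt - filt.mean(axis=2, keepdims=True)
    return np.einsum("tcs,tds->cd", filt, filt) / (filt.shape[0] * filt.shape[2])


def _beamform_weights(forward: ToyForwardModel, C: np.ndarray,
                      lambda_frac: float, kind: str) -> SpatialFilter:
    n = C.shape[0]
    reg = lambda_frac * float(np.mean(np.real(np.diag(C))))
    Creg = C + reg * np.eye(n)
    try:
        Cinv = np.linalg.inv(Creg)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"regularized CSD is singular (cond={np.linalg.cond(Creg):.3g})") from err

    weights = np.empty((forward.n_sources, n), dtype=Cinv.dtype)
    oris = np.empty((forward.n_sources, 3))
    for j in range(forward.n_sources):
        L = forward.leadfield_for(j)                   # (n_sensors, 3)
        G = L.conj().T @ Cinv @ L                      # (3, 3)
        # dominant orientation: maximal output power direction, i.e. the
        # eigenvector of the smallest eigenvalue of the real part of G
        evals, evecs = np.linalg.eigh(np.real(G))
        u = evecs[:, 0]
        if u[np.argmax(np.abs(u))] < 0:                # deterministic sign
            u = -u
        l = L @ u                                      # (n_sensors,)
        denom = l.conj() @ Cinv @ l
        weights[j] = (Cinv @ l).conj() / denom         # w = l^H Cinv / (l^H Cinv l)
        oris[j] = u
    return SpatialFilter(weights, lambda_frac, kind, oris)


def dics_filter(forward: ToyForwardModel, csd_: CrossSpectralDensity,
                lambda_frac: float = 0.10) -> SpatialFilter:
    """DICS common spatial filter from a regularized CSD.

    Unit gain: w @ l(source) = 1 on the reduced orientation.  Regularization
    adds ``lambda_frac`` of the mean sensor power to the diagonal.
    """
    return _beamform_weights(forward, csd_.matrix, lambda_frac, "dics")


def lcmv_filter(forward: ToyForwardModel, covariance: np.ndarray,
                lambda_frac: float = 0.10) -> SpatialFilter:
    """LCMV spatial filter from a (band-limited) real covariance matrix."""
    cov = np.asarray(covariance, float)
    return _beamform_weights(forward, cov, lambda_frac, "lcmv")


def project_trials(filt: SpatialFilter, trials: np.ndarray) -> np.ndarray:
    """Virtual-channel time series: (n_trials, n_sources, n_samples)."""
    W = np.real_if_close(filt.weights)
    return np.einsum("vc,tcs->tvs", np.real(W), np.asarray(trials, float))


def source_power_contrast(filt: SpatialFilter, trials: np.ndarray, fs_hz: float,
                          t_start_s: float, target_hz: float,
                          offsets: tuple[int, ...] = DEFAULT_OFFSETS,
                          taper: str = "hann",
                          analysis_window_s: tuple[float, float] = (0.5, 9.5),
                          fmin_hz: float = 1.0, fmax_hz: float = 7.0
                          ) -> tuple[np.ndarray, SpectrumMap]:
    """Beamformed power spectrum per source and its neighbor-bin contrast.

    Power at bin f per source j is w_j^H S(f) w_j with S(f) the trial-
    averaged sensor cross-spectral matrix at that bin, evaluated via the
    projected Fourier coefficients.
    """
    coeff, freqs = _fourier_coefficients(trials, fs_hz, t_start_s,
                                         analysis_window_s, taper)
    sel = np.flatnonzero((freqs >= fmin_hz - 1e-9) & (freqs <= fmax_hz + 1e-9))
    proj = np.einsum("vc,tcb->tvb", filt.weights, coeff[:, :, sel])
    power = np.mean(np.abs(proj) ** 2, axis=0)        # (n_sources, n_bins)
    spec = SpectrumMap(power, freqs[sel], kind="power", space="source")
    return neighbor_bin_contrast(spec, target_hz, offsets), spec


def roi_average(values: np.ndarray, rois: dict[str, np.ndarray],
                axis: int = 0) -> dict[str, np.ndarray]:
    """Arithmetic mean over each ROI's source indices along ``axis``."""
    values = np.asarray(values)
    return {name: values.take(idx, axis=axis).mean(axis=axis)
            for name, idx in rois.items()}
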