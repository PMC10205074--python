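"""Evoked power spectra at the tagging resolution and neighbor-bin contrasts.

Power is computed on the time-domain trial average (evoked) over a 9 s
analysis window, giving a frequency resolution of 1/9 s = 0.1111 Hz so
that 2 Hz and 4 Hz fall exactly on spectral bins.  Tagging responses are
quantified as the power at the target bin minus the mean power at the
neighboring bins (offsets -3, -2, +2, +3 by default; +-1 is excluded to
avoid leakage from the target bin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import signal

__all__ = ["SpectrumMap", "evoked_spectrum", "neighbor_bin_contrast",
           "jackknife_trial_power", "block_trend"]

DEFAULT_OFFSETS = (-3, -2, 2, 3)


@dataclass
class SpectrumMap:
    """Per-channel (or per-voxel) values on a uniform frequency grid."""

    values: np.ndarray      # (n_channels, n_bins)
    freqs_hz: np.ndarray    # (n_bins,)
    kind: str = "power"     # power | contrast | coherence | mi
    space: str = "sensor"   # sensor | source

    def __post_init__(self) -> None:
        d = np.diff(self.freqs_hz)
        if self.freqs_hz.size > 1 and (np.any(d <= 0) or not np.allclose(d, d[0])):
            raise ValueError("frequency bins must be strictly increasing and uniform")
        if self.kind == "power" and np.any(self.values < 0):
            raise ValueError("power values must be non-negative")

    def bin_index(self, target_hz: float, tol_hz: float = 1e-6) -> int:
        i = int(np.argmin(np.abs(self.freqs_hz - target_hz)))
        if abs(self.freqs_hz[i] - target_hz) > tol_hz:
            raise ValueError(f"{target_hz} Hz is not on the frequency grid")
        return i


def _taper(name: str, n: int) -> np.ndarray:
    if name == "hann":
        return np.hanning(n)
    if name == "dpss":
        return signal.windows.dpss(n, NW=1.0)
    if name == "boxcar":
        return np.ones(n)
    raise ValueError(f"unknown taper: {name!r}")


def evoked_spectrum(trials: np.ndarray, fs_hz: float, t_start_s: float,
                    analysis_window_s: tuple[float, float] = (0.5, 9.5),
                    taper: str = "hann",
                    fmin_hz: float = 1.0, fmax_hz: float = 7.0,
                    space: str = "sensor") -> SpectrumMap:
    """Single-taper power spectrum of the time-domain trial average.

    The 9 s analysis window sets the bin spacing to 0.1111 Hz; the first
    0.5 s after stimulus onset is excluded to avoid onset contamination.
    Power is normalized as a periodogram density, so the sum of power
    times bin width equals the (tapered) time-domain variance.
    """
    trials = np.asarray(trials, float)
    if trials.ndim == 2:
        trials = trials[None]
    n_samp = trials.shape[2]
    i0 = round((analysis_window_s[0] - t_start_s) * fs_hz)
    i1 = round((analysis_window_s[1] - t_start_s) * fs_hz)
    if i0 < 0 or i1 > n_samp:
        raise ValueError("analysis window not inside the epoch")
    evoked = trials.mean(axis=0)[:, i0:i1]
    n = evoked.shape[1]
    freqs, power = signal.periodogram(evoked, fs=fs_hz, window=_taper(taper, n),
                                      detrend="constant", axis=-1)
    sel = (freqs >= fmin_hz - 1e-9) & (freqs <= fmax_hz + 1e-9)
    return SpectrumMap(power[:, sel], freqs[sel], kind="power", space=space)


def neighbor_bin_contrast(spec: SpectrumMap, target_hz: float,
                          offsets: tuple[int, ...] = DEFAULT_OFFSETS,
                          relative: bool = False) -> np.ndarray:
    """Target-bin value minus the mean of the neighboring bins, per channel.

    With ``relative``, returns (target - neighbors) / neighbors instead.
    """
    i = spec.bin_index(target_hz)
    idx = np.array(offsets) + i
    if idx.min() < 0 or idx.max() >= spec.freqs_hz.size:
        raise ValueError("neighbor offsets fall outside the spectrum")
    target = spec.values[:, i]
    neigh = spec.values[:, idx].mean(axis=1)
    if relative:
        return (target - neigh) / neigh
    return target - neigh


def jackknife_trial_power(trials: np.ndarray, fs_hz: float, t_start_s: float,
                          target_hz: float, sensors: np.ndarray | None = None,
                          analysis_window_s: tuple[float, float] = (0.5, 9.5),
                          taper: str = "hann",
                          offsets: tuple[int, ...] = DEFAULT_OFFSETS,
                          pseudo_values: bool = False) -> np.ndarray:
    """Leave-one-out evoked power contrast per trial.

    Value i is the neighbor-bin contrast of the evoked spectrum computed
    from all trials except i, averaged over ``sensors`` (all by default).
    Leave-one-out values are anti-correlated with the left-out trial's own
    contribution; with ``pseudo_values`` the jackknife pseudo-values
    n*full - (n-1)*loo are returned instead, which are sign-correct
    trial-wise estimates (use these when fitting trends over trials).
    """
    trials = np.asarray(trials, float)
    n = trials.shape[0]
    if n < 2:
        raise ValueError("jackknife needs at least two trials")

    def contrast(avg: np.ndarray) -> float:
        spec = evoked_spectrum(avg[None], fs_hz, t_start_s, analysis_window_s, taper)
        c = neighbor_bin_contrast(spec, target_hz, offsets)
        return float(c.mean() if sensors is None else c[sensors].mean())

    total = trials.sum(axis=0)
    out = np.empty(n)
    for i in range(n):
        out[i] = contrast((total - trials[i]) / (n - 1))
    if pseudo_values:
        full = contrast(total / n)
        out = n * full - (n - 1) * out
    return out


def _orthogonal_design(block: np.ndarray, order: int) -> np.ndarray:
    """Orthonormal polynomial design (constant, linear, ... ) via QR.

    Column signs are fixed so the highest-order raw coefficient of each
    polynomial is positive; a negative fitted quadratic coefficient then
    means inverted-U curvature.
    """
    b = np.asarray(block, float)
    bc = (b - b.mean()) / (b.std() if b.std() else 1.0)
    raw = np.column_stack([bc ** k for k in range(order + 1)])
    q, r = np.linalg.qr(raw)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return q * signs


def block_trend(jk_values: np.ndarray, block_index: np.ndarray,
                poly_order: int = 2) -> dict:
    """Polynomial trend of jackknife power across blocks, with BIC comparison.

    Fits OLS with orthogonal polynomial terms of block order for every
    order from 1 to ``poly_order`` and selects the minimum-BIC model.
    Returns per-order coefficient estimates, standard errors, t, p and
    BIC, plus the selected order.
    """
    y = np.asarray(jk_values, float)
    block = np.asarray(block_index, float)
    if poly_order not in (1, 2):
        raise ValueError("poly_order must be 1 or 2")
    if np.unique(block).size < poly_order + 1:
        raise ValueError("need more distinct blocks than the polynomial order")
    models = {}
    for order in range(1, poly_order + 1):
        X = _orthogonal_design(block, order)
        fit = sm.OLS(y, X).fit()
        models[order] = {
            "coef": fit.params[1:],          # polynomial terms (constant excluded)
            "se": fit.bse[1:],
            "t": fit.tvalues[1:],
            "p": fit.pvalues[1:],
            "bic": float(fit.bic),
            "fitted": fit.fittedvalues,
        }
    selected = min(models, key=lambda k: models[k]["bic"])
    return {"models": models, "selected_order": selected}
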