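"""Bioluminescence processing: binning, decay detrending, and Morlet
wavelet period estimation.

The analysis chain mirrors the standard luciferase workflow: raw counts
per second are averaged into 30-min bins, the exponential decay of the
luciferin signal is divided out, a 24-h moving average removes residual
baseline, and a continuous Morlet wavelet transform over a 16–32 h period
band yields a time-resolved period ridge whose median is the period
estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["LucSeries", "WaveletResult", "bin_luminescence",
           "detrend_luminescence", "wavelet_period", "morlet_cwt"]

MORLET_OMEGA0 = 6.0
# conversion between Fourier period and Morlet scale (Torrence & Compo)
_PERIOD_PER_SCALE = 4 * np.pi / (MORLET_OMEGA0 + np.sqrt(2 + MORLET_OMEGA0 ** 2))


@dataclass
class LucSeries:
    """Uniformly sampled bioluminescence trace (counts per second)."""

    sample_id: str
    genotype: str
    t: np.ndarray  # hours from start
    cps: np.ndarray
    resolution: float  # minutes

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.cps = np.asarray(self.cps, dtype=float)
        if self.t.shape != self.cps.shape:
            raise ValueError("t and cps must have equal length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("sampling must be uniform")

    @property
    def duration_hours(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0


@dataclass
class WaveletResult:
    """Time-resolved period ridge and its summary for one sample."""

    sample_id: str
    t_ridge: np.ndarray  # hours; points inside the cone of influence only
    period_ridge: np.ndarray  # hours
    median_period: float
    band: tuple[float, float]
    no_signal: bool = False


def bin_luminescence(raw: LucSeries, bin_minutes: float = 30.0) -> LucSeries:
    """Average cps into fixed-width time bins.

    Samples are assigned by timestamp, so the bin width need not be an
    integer multiple of the sampling resolution (4-min samples in 30-min
    bins alternate between 7 and 8 per bin).  A trailing partial bin is
    dropped.
    """
    if bin_minutes < raw.resolution:
        raise ValueError("bin width must be at least the sampling resolution")
    bin_h = bin_minutes / 60.0
    rel = raw.t - raw.t[0]
    idx = np.floor(rel / bin_h + 1e-9).astype(int)
    n_bins = int((rel[-1] + raw.resolution / 60.0) / bin_h + 1e-9)
    if n_bins < 1:
        raise ValueError("record shorter than one bin")
    keep = idx < n_bins
    sums = np.bincount(idx[keep], weights=raw.cps[keep], minlength=n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    cps = sums / counts
    t = raw.t[0] + np.arange(n_bins) * bin_h
    return replace(raw, t=t, cps=cps, resolution=bin_minutes)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge windows truncated, not padded."""
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detrend_luminescence(series: LucSeries,
                         trend_window_hours: float = 24.0) -> LucSeries:
    """Remove exponential decay and residual baseline.

    Fits ``cps ~ A exp(-t/lambda)`` by least squares on the log signal,
    divides the raw signal by the fit, and subtracts a centered 24-h
    moving average so the output oscillates around zero.  When the raw
    signal has non-positive values the log fit falls back to the 24-h
    smoothed signal (offset-shifted if needed) with a warning.  Output
    values can be negative by construction.
    """
    if series.duration_hours < 48.0:
        raise ValueError("detrending requires at least 2 days of data")
    bins_per_window = int(round(trend_window_hours * 60 / series.resolution))
    if bins_per_window % 2 == 0:
        bins_per_window += 1
    target = series.cps
    if not np.all(target > 0):
        warnings.warn("non-positive values; fitting decay on smoothed signal")
        target = _moving_average(series.cps, bins_per_window)
        if not np.all(target > 0):
            target = target - target.min() + np.abs(target).max() * 1e-6
    slope, intercept = np.polyfit(series.t, np.log(target), 1)
    fit = np.exp(intercept + slope * series.t)
    ratio = series.cps / fit
    detrended = ratio - _moving_average(ratio, bins_per_window)
    return replace(series, cps=detrended)


def morlet_cwt(x: np.ndarray, dt_hours: float,
               periods: np.ndarray) -> np.ndarray:
    """Continuous Morlet (omega0=6) wavelet transform via FFT.

    Returns complex coefficients of shape (len(periods), len(x)).
    """
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(n * 2)))
    xf = np.fft.fft(x, nfft)
    omega = 2 * np.pi * np.fft.fftfreq(nfft, d=dt_hours)
    scales = np.asarray(periods) / _PERIOD_PER_SCALE
    # frequency-domain Morlet, analytic (positive frequencies only)
    arg = scales[:, None] * omega[None, :] - MORLET_OMEGA0
    psi_hat = (np.pi ** -0.25) * np.exp(-0.5 * arg ** 2) * (omega[None, :] > 0)
    norm = np.sqrt(2 * np.pi * scales / dt_hours)
    W = np.fft.ifft(xf[None, :] * psi_hat.conj() * norm[:, None], axis=1)
    return W[:, :n]


def wavelet_period(detrended: LucSeries,
                   band: tuple[float, float] = (16.0, 32.0),
                   n_voices: int = 64) -> WaveletResult:
    """Time-resolved period via the power ridge of a Morlet transform.

    Uses ``n_voices`` log-spaced periods inside ``band``; per time point
    the ridge is the power-maximizing period (refined by parabolic
    interpolation in log period).  Points where the ridge scale falls
    outside the cone of influence are excluded; the summary period is the
    median over the remaining ridge.
    """
    lo, hi = band
    if detrended.duration_hours < 3 * hi:
        raise ValueError("record must span at least 3x the longest band period")
    x = detrended.cps - np.mean(detrended.cps)
    if np.allclose(x, 0):
        return WaveletResult(detrended.sample_id, np.array([]), np.array([]),
                             float("nan"), band, no_signal=True)
    dt = detrended.resolution / 60.0
    periods = np.geomspace(lo, hi, n_voices)
    W = morlet_cwt(x, dt, periods)
    power = np.abs(W) ** 2
    t_rel = detrended.t - detrended.t[0]
    dist_edge = np.minimum(t_rel, t_rel[-1] - t_rel)  # hours to nearest edge
    scales = periods / _PERIOD_PER_SCALE
    coi_ok = (np.sqrt(2.0) * scales)[:, None] <= dist_edge[None, :]
    power = np.where(coi_ok, power, -np.inf)
    # keep only times where the whole band is inside the cone, otherwise
    # the ridge is forced onto whatever short periods remain admissible
    valid_t = coi_ok.all(axis=0)
    ridge_idx = np.argmax(power, axis=0)
    log_p = np.log(periods)
    ridge = np.empty(len(x))
    for i in np.flatnonzero(valid_t):
        k = ridge_idx[i]
        if 0 < k < n_voices - 1 and np.isfinite(power[k - 1, i]) \
                and np.isfinite(power[k + 1, i]):
            y0, y1, y2 = power[k - 1, i], power[k, i], power[k + 1, i]
            denom = y0 - 2 * y1 + y2
            shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            ridge[i] = np.exp(log_p[k] + shift * (log_p[1] - log_p[0]))
        else:
            ridge[i] = periods[k]
    t_ridge = detrended.t[valid_t]
    period_ridge = ridge[valid_t]
    return WaveletResult(
        sample_id=detrended.sample_id, t_ridge=t_ridge,
        period_ridge=period_ridge,
        median_period=float(np.median(period_ridge)), band=band)
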