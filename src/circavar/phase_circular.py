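"""Per-fly free-running activity-peak phases and the circular statistics
that quantify group phase coherence.

Phase is extracted on DD days 2 and 3: each day's counts are low-pass
filtered (zero-phase Butterworth applied circularly), the circadian time
of the smoothed maximum is converted to an angle, and the two daily
phases are combined by circular mean.  Coherence is 1 / circular SD,
with circular SD = sqrt(-2 ln Rbar).  Hypothesis tests: Watson's U^2
goodness of fit against the fitted Von Mises (parametric bootstrap
p-values) and the pairwise equal-concentration test with three
variance-stabilizing regimes chosen by the pooled resultant length,
Bonferroni-adjusted across pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import signal
from scipy.special import i0e, i1e
from scipy.stats import chi2, vonmises

from .dam_io import ActivitySeries

__all__ = [
    "PhaseSample", "CircularSummary", "TestResult",
    "daily_peak_phase", "fly_phase", "circular_summary",
    "watson_gof", "equal_kappa_pairwise",
    "circular_mean", "resultant_length", "kappa_ml",
]


@dataclass
class PhaseSample:
    fly_id: str
    genotype: str
    phase: float  # radians in [0, 2pi)
    source_days: tuple[int, ...] = (2, 3)


@dataclass
class CircularSummary:
    n: int
    mu: float  # mean direction, radians
    rbar: float
    circ_sd: float  # sqrt(-2 ln rbar)
    kappa: float
    median: float
    coherence: float  # 1 / circ_sd; inf when rbar == 1
    degenerate: bool = False  # all angles identical


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    groups: tuple[str, ...] = ()
    note: str = ""


# ---------------------------------------------------------------------------
# basic circular quantities


def circular_mean(theta: np.ndarray) -> float:
    theta = np.asarray(theta, dtype=float)
    return float(np.arctan2(np.sin(theta).sum(), np.cos(theta).sum()) % (2 * np.pi))


def resultant_length(theta: np.ndarray) -> float:
    theta = np.asarray(theta, dtype=float)
    return float(np.hypot(np.sin(theta).mean(), np.cos(theta).mean()))


def _a1(kappa):
    """A(kappa) = I1(kappa) / I0(kappa), safe for large kappa."""
    return i1e(kappa) / i0e(kappa)


def kappa_ml(rbar, n: int | None = None):
    """Maximum-likelihood Von Mises concentration from Rbar.

    Starts from the standard piecewise series approximation and refines by
    Newton steps on A(kappa) = Rbar.  Vectorized.
    """
    rbar = np.asarray(rbar, dtype=float)
    scalar = rbar.ndim == 0
    r = np.atleast_1d(rbar).astype(float)
    k = np.where(
        r < 0.53, 2 * r + r ** 3 + 5 * r ** 5 / 6,
        np.where(r < 0.85, -0.4 + 1.39 * r + 0.43 / np.maximum(1 - r, 1e-12),
                 1.0 / np.maximum(r ** 3 - 4 * r ** 2 + 3 * r, 1e-12)))
    k = np.clip(k, 0.0, 1e8)
    refine = (r > 0) & (r < 1 - 1e-12)
    for _ in range(5):
        a = _a1(k)
        # d/dk A(k) = 1 - A/k - A^2
        deriv = np.where(k > 1e-8, 1 - a / np.maximum(k, 1e-8) - a ** 2, 0.5)
        step = np.where(refine & (deriv > 1e-12), (a - r) / np.maximum(deriv, 1e-12), 0.0)
        k = np.clip(k - step, 0.0, 1e8)
    k = np.where(r <= 1e-12, 0.0, k)
    k = np.where(r >= 1 - 1e-12, np.inf, k)
    return float(k[0]) if scalar else k


def _circular_median(theta: np.ndarray) -> float:
    """Data angle minimizing the mean arc distance; ties (the even-n
    central pair) are resolved by the circular mean of the tied angles,
    which keeps the median rotation-equivariant."""
    theta = np.asarray(theta, dtype=float) % (2 * np.pi)
    d = np.abs(np.pi - np.abs(np.pi - np.abs(theta[None, :] - theta[:, None])))
    obj = d.mean(axis=1)
    tied = theta[obj <= obj.min() + 1e-12]
    return circular_mean(tied)


# ---------------------------------------------------------------------------
# phase extraction


def daily_peak_phase(series: ActivitySeries, day: int, segment: str = "DD",
                     cutoff_period_h: float = 4.0) -> float | None:
    """Circadian time of the smoothed activity maximum of one day, as an
    angle theta = 2 pi zt / 24.

    The day's counts are low-pass filtered with a zero-phase second-order
    Butterworth (cutoff period ``cutoff_period_h``) applied circularly
    (filtering three tiled copies and keeping the middle one) so a peak at
    the day boundary is not distorted.  Returns None for an all-zero day.
    """
    sl = series.day_slice(segment, day)
    counts = np.asarray(series.counts[sl], dtype=float)
    zt = series.zt[sl]
    if counts.sum() == 0:
        return None
    fs = 60.0 / series.bin_width  # samples per hour
    wn = (1.0 / cutoff_period_h) / (fs / 2.0)
    sos = signal.butter(2, wn, btype="low", output="sos")
    tiled = np.tile(counts, 3)
    smooth = signal.sosfiltfilt(sos, tiled)[len(counts):2 * len(counts)]
    return float(2 * np.pi * zt[int(np.argmax(smooth))] / 24.0)


def fly_phase(series: ActivitySeries, days: tuple[int, int] = (2, 3),
              segment: str = "DD") -> PhaseSample | None:
    """Circular mean of the daily peak phases on DD2 and DD3.

    One missing day falls back to the other; both missing excludes the
    fly (returns None).
    """
    phases, used = [], []
    for day in days:
        try:
            p = daily_peak_phase(series, day, segment=segment)
        except Exception:
            p = None
        if p is not None:
            phases.append(p)
            used.append(day)
    if not phases:
        return None
    return PhaseSample(fly_id=series.fly_id, genotype=series.genotype,
                       phase=circular_mean(np.array(phases)),
                       source_days=tuple(used))


# ---------------------------------------------------------------------------
# summaries and tests


def _phases_array(phases) -> np.ndarray:
    if len(phases) and isinstance(phases[0], PhaseSample):
        return np.array([p.phase for p in phases], dtype=float)
    return np.asarray(phases, dtype=float)


def circular_summary(phases) -> CircularSummary:
    """Group-level circular statistics; coherence = 1 / circular SD."""
    theta = _phases_array(phases)
    n = len(theta)
    if n < 2:
        raise ValueError("need at least 2 phases")
    rbar = resultant_length(theta)
    mu = circular_mean(theta)
    if rbar >= 1 - 1e-12:
        return CircularSummary(n=n, mu=mu, rbar=1.0, circ_sd=0.0,
                               kappa=float("inf"), median=_circular_median(theta),
                               coherence=float("inf"), degenerate=True)
    circ_sd = math.sqrt(-2 * math.log(rbar)) if rbar > 0 else float("inf")
    kappa = kappa_ml(rbar)
    coherence = 1.0 / circ_sd if circ_sd > 0 else float("inf")
    return CircularSummary(n=n, mu=mu, rbar=rbar, circ_sd=circ_sd,
                           kappa=float(kappa), median=_circular_median(theta),
                           coherence=coherence)


def _watson_u2(theta: np.ndarray, mu: float, kappa: float) -> float:
    """Watson U^2 of a sample against Von Mises(mu, kappa)."""
    n = len(theta)
    x = ((theta - mu + np.pi) % (2 * np.pi)) - np.pi
    z = np.sort(vonmises.cdf(x, kappa))
    i = np.arange(1, n + 1)
    return float(np.sum((z - (2 * i - 1) / (2 * n)) ** 2)
                 + 1 / (12 * n) - n * (z.mean() - 0.5) ** 2)


def watson_gof(phases, n_boot: int = 1000, seed: int | None = None) -> TestResult:
    """Watson's goodness-of-fit test against the fitted Von Mises.

    The p-value is a parametric bootstrap: ``n_boot`` samples are drawn
    from VM(mu_hat, kappa_hat), each refitted, and U^2 recomputed.
    """
    theta = _phases_array(phases)
    n = len(theta)
    note = ""
    if n < 10:
        warnings.warn("n < 10: Watson test is underpowered")
        note = "n < 10"
    rbar = resultant_length(theta)
    if rbar >= 1 - 1e-12:
        return TestResult("watson_gof", float("nan"), float("nan"),
                          note="degenerate sample: all phases identical")
    mu, kappa = circular_mean(theta), float(kappa_ml(rbar))
    u2_obs = _watson_u2(theta, mu, kappa)
    rng = np.random.default_rng(seed)
    boot = rng.vonmises(mu, kappa, size=(n_boot, n))
    s, c = np.sin(boot), np.cos(boot)
    mu_b = np.arctan2(s.sum(axis=1), c.sum(axis=1))
    rbar_b = np.hypot(s.mean(axis=1), c.mean(axis=1))
    kappa_b = kappa_ml(np.clip(rbar_b, 0, 1 - 1e-12))
    x = ((boot - mu_b[:, None] + np.pi) % (2 * np.pi)) - np.pi
    z = np.sort(vonmises.cdf(x, kappa_b[:, None]), axis=1)
    i = np.arange(1, n + 1)
    u2_b = (np.sum((z - (2 * i - 1) / (2 * n)) ** 2, axis=1)
            + 1 / (12 * n) - n * (z.mean(axis=1) - 0.5) ** 2)
    p = (1 + np.sum(u2_b >= u2_obs)) / (n_boot + 1)
    return TestResult("watson_gof", u2_obs, float(p), note=note)


def _equal_kappa_stat(ns: np.ndarray, rbars: np.ndarray) -> tuple[float, int, str]:
    """Concentration-homogeneity chi-square statistic across groups.

    Three variance-stabilizing regimes selected by the pooled mean
    resultant length: arcsine (< 0.45), inverse-sinh (0.45–0.70), and a
    Bartlett-type statistic on the residual lengths (> 0.70).
    """
    p = len(ns)
    n = ns.sum()
    rbar_all = float(np.sum(ns * rbars) / n)
    if rbar_all < 0.45:
        g = np.arcsin(np.clip(np.sqrt(1.5) * rbars, -1, 1))
        w = 4 * (ns - 4) / 3
        stat = float(np.sum(w * g ** 2) - np.sum(w * g) ** 2 / np.sum(w))
        regime = "rbar<0.45"
    elif rbar_all <= 0.70:
        g = np.arcsinh((rbars - 1.089) / 0.258)
        w = (ns - 3) / 0.798 ** 2
        stat = float(np.sum(w * g ** 2) - np.sum(w * g) ** 2 / np.sum(w))
        regime = "0.45<=rbar<=0.70"
    else:
        R = ns * rbars
        vs = ns - 1
        v = n - p
        d = (np.sum(1 / vs) - 1 / v) / (3 * (p - 1))
        stat = float((v * np.log((n - R.sum()) / v)
                      - np.sum(vs * np.log((ns - R) / vs))) / (1 + d))
        regime = "rbar>0.70"
    return stat, p - 1, regime


def equal_kappa_pairwise(groups: dict[str, np.ndarray],
                         min_n: int = 5) -> list[TestResult]:
    """Pairwise equal-concentration tests with Bonferroni adjustment.

    ``groups`` maps genotype to an array of phases (or PhaseSamples).
    Pairs in which either group has n < ``min_n`` are skipped with a
    notice.  p_adjusted = min(1, m * p) over the m tested pairs.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    clean = {g: _phases_array(v) for g, v in groups.items()}
    results: list[TestResult] = []
    tested: list[TestResult] = []
    for g1, g2 in combinations(clean, 2):
        t1, t2 = clean[g1], clean[g2]
        if len(t1) < min_n or len(t2) < min_n:
            results.append(TestResult("equal_kappa", float("nan"), float("nan"),
                                      groups=(g1, g2),
                                      note=f"skipped: group below n={min_n}"))
            continue
        ns = np.array([len(t1), len(t2)], dtype=float)
        rbars = np.array([resultant_length(t1), resultant_length(t2)])
        stat, df, regime = _equal_kappa_stat(ns, rbars)
        p = float(chi2.sf(max(stat, 0.0), df))
        res = TestResult("equal_kappa", stat, p, groups=(g1, g2), note=regime)
        results.append(res)
        tested.append(res)
    m = len(tested)
    for r in tested:
        r.p_adjusted = min(1.0, m * r.p_value)
    return results
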