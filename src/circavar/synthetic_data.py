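"""Synthetic data generators mirroring the statistical structure the
analysis assumes: per-fly activity counts from a periodic two-state
switching process with random intercepts and negative-binomial emissions,
exponentially decaying oscillatory luciferase traces, and two-group
intensity samples.

Per-fly heterogeneity beyond the random intercepts: a circular phase
offset (Von Mises) shifts each fly's switching-probability clock, and in
DD a per-fly free-running period dilates it, producing the phase
incoherence phenotypes the downstream statistics are built to detect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime

import numpy as np

from .activity_hmm import HMMSpec, NBParams, periodic_stationary, transition_matrices
from .dam_io import ActivitySeries, PhotoRegime, annotate_regime
from .luc_wavelet import LucSeries

__all__ = ["GenotypeSimParams", "SimulatedDataset", "simulate_activity",
           "simulate_luciferase", "simulate_intensity"]

_T0 = datetime(2024, 1, 1)


@dataclass(frozen=True)
class GenotypeSimParams:
    """Generative parameters for one genotype's activity simulation.

    Emission means/dispersions follow the (mean, dispersion) negative
    binomial convention (variance mu + mu^2/phi).  ``beta12``/``beta21``
    are logit-scale harmonic coefficients (beta0, a1, b1, ...) for the
    inactive->active and active->inactive switching probabilities.
    """

    genotype: str
    n_flies: int
    mu: tuple[float, float] = (0.5, 12.0)
    phi: tuple[float, float] = (2.0, 5.0)
    beta12: tuple[float, ...] = (-2.5, 1.0, 0.0)
    beta21: tuple[float, ...] = (-1.5, 0.0, 0.0)
    sigma_u: float = 0.0
    kappa_phase: float = float("inf")
    tau_free_mean: float = 24.0
    tau_free_sd: float = 0.0
    startle_counts: int = 0
    masking_factor: float = 1.0

    def __post_init__(self):
        if self.mu[1] < self.mu[0] or self.mu[0] < 0:
            raise ValueError("need 0 <= mu_inactive <= mu_active")
        if min(self.phi) <= 0:
            raise ValueError("dispersions must be positive")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be non-negative")
        if self.kappa_phase < 0:
            raise ValueError("kappa_phase must be non-negative")
        if not 18 < self.tau_free_mean < 30:
            raise ValueError("tau_free_mean must lie in (18, 30)")

    def spec(self, bin_width: int = 30, segment: str = "LD") -> HMMSpec:
        """The HMM this genotype generates, at zero random intercepts."""
        return HMMSpec(
            emissions=NBParams(mu=np.array(self.mu), phi=np.array(self.phi),
                               segment=segment),
            beta12=np.array(self.beta12), beta21=np.array(self.beta21),
            sigma_u=self.sigma_u, bin_width=bin_width)


@dataclass
class SimulatedDataset:
    """Simulated series plus the generating truth, reproducible by seed."""

    series_set: list[ActivitySeries]
    true_states: list[np.ndarray]  # 0 = inactive, 1 = active
    true_intercepts: np.ndarray  # (n_flies, 2) = (u12, u21)
    true_phases: np.ndarray  # radians
    true_periods: np.ndarray  # hours, DD free-running
    seed: int
    params: GenotypeSimParams = None
    regime: PhotoRegime = None


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             phi: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion) sample via the gamma–Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    lam = np.where(mean > 0,
                   rng.gamma(shape=phi, scale=np.maximum(mean, 1e-300) / phi),
                   0.0)
    return rng.poisson(lam)


def simulate_activity(params: GenotypeSimParams, regime: PhotoRegime,
                      seed: int, bin_width: int = 30) -> SimulatedDataset:
    """Simulate one genotype's flies under an LD→DD protocol.

    Per fly: random intercepts (u12, u21) ~ N(0, sigma_u^2) shift both
    switching logits; a Von Mises phase offset rotates the covariate
    clock; in DD a per-fly period tau_i dilates it.  Counts are negative
    binomial given the state, with an optional masking multiplier on the
    mean in dark bins and a fixed startle count added to the first bin
    after each light transition.
    """
    rng = np.random.default_rng(seed)
    n_days = regime.n_ld_days + regime.n_dd_days
    bins_per_day = (24 * 60) // bin_width
    T = n_days * bins_per_day
    t0_h = int(regime.lights_on)
    t0_m = int(round((regime.lights_on - t0_h) * 60))
    t0 = _T0.replace(hour=t0_h, minute=t0_m)
    template = ActivitySeries(fly_id="", genotype=params.genotype,
                              bin_width=bin_width, t0=t0,
                              counts=np.zeros(T, dtype=int))
    template = annotate_regime(template, regime)
    zt = template.zt
    is_dd = template.segment == "DD"
    dark = template.light == "D"
    hours = template.times
    dd_start = hours[is_dd][0] if is_dd.any() else 0.0
    spec0 = params.spec(bin_width=bin_width)

    intercepts = rng.normal(0.0, params.sigma_u, size=(params.n_flies, 2))
    if np.isinf(params.kappa_phase):
        phases = np.zeros(params.n_flies)
    elif params.kappa_phase == 0:
        phases = rng.uniform(0, 2 * np.pi, size=params.n_flies)
    else:
        phases = rng.vonmises(0.0, params.kappa_phase, size=params.n_flies) % (2 * np.pi)
    periods = np.clip(rng.normal(params.tau_free_mean, params.tau_free_sd,
                                 size=params.n_flies), 18.001, 29.999)

    # startle lands in the first bin holding the new light state
    trans_bins = np.flatnonzero(np.asarray(template.light[1:]) != np.asarray(template.light[:-1])) + 1

    series_set: list[ActivitySeries] = []
    state_list: list[np.ndarray] = []
    mu = np.array(params.mu)
    phi = np.array(params.phi)
    for i in range(params.n_flies):
        phase_h = phases[i] * 24.0 / (2 * np.pi)
        clock = np.where(is_dd, ((hours - dd_start) * 24.0 / periods[i]) % 24.0, zt)
        clock = (clock - phase_h) % 24.0
        gam = transition_matrices(spec0, clock, intercepts[i])  # (T, 2, 2)
        # initial state from the stationary distribution of the first cycle
        delta0 = periodic_stationary(gam[None, :bins_per_day])[0, 0]
        states = np.empty(T, dtype=int)
        states[0] = rng.choice(2, p=delta0)
        u = rng.uniform(size=T - 1)
        for t in range(1, T):
            p_switch = gam[t - 1, states[t - 1], 1 - states[t - 1]]
            states[t] = states[t - 1] if u[t - 1] >= p_switch else 1 - states[t - 1]
        mean_t = mu[states] * np.where(dark, params.masking_factor, 1.0)
        counts = _nb_draw(rng, mean_t, phi[states])
        if params.startle_counts:
            counts[trans_bins] += params.startle_counts
        s = ActivitySeries(fly_id=f"{params.genotype}_{i:03d}",
                           genotype=params.genotype, bin_width=bin_width,
                           t0=t0, counts=counts, light=template.light,
                           zt=zt, segment=template.segment)
        series_set.append(s)
        state_list.append(states)
    return SimulatedDataset(series_set=series_set, true_states=state_list,
                            true_intercepts=intercepts, true_phases=phases,
                            true_periods=periods, seed=seed, params=params,
                            regime=regime)


def simulate_luciferase(amplitude: float, decay_constant: float,
                        period: float, modulation: float, noise_sd: float,
                        duration_days: float, resolution_minutes: float,
                        seed: int, phase: float = 0.0,
                        sample_id: str = "luc", genotype: str = "") -> LucSeries:
    """Exponentially decaying oscillatory trace:
    S(t) = A exp(-t/lambda) (1 + m cos(2 pi t / tau + phase)) + noise.
    """
    if not 16 < period < 32:
        raise ValueError("period must lie in (16, 32) h")
    if modulation >= 1:
        raise ValueError("modulation must be < 1 (signal would go negative)")
    res_per_day = 24 * 60 / resolution_minutes
    if abs(res_per_day - round(res_per_day)) > 1e-9:
        raise ValueError("resolution must divide 24 h")
    rng = np.random.default_rng(seed)
    n = int(round(duration_days * res_per_day))
    t = np.arange(n) * resolution_minutes / 60.0
    signal = amplitude * np.exp(-t / decay_constant) * (
        1 + modulation * np.cos(2 * np.pi * t / period + phase))
    if noise_sd > 0:
        signal = np.maximum(signal + rng.normal(0, noise_sd, size=n), 0.0)
    return LucSeries(sample_id=sample_id, genotype=genotype, t=t, cps=signal,
                     resolution=resolution_minutes)


def simulate_intensity(mean_a: float, mean_b: float, sd: float,
                       n_a: int, n_b: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Two Normal staining-intensity samples with a common SD."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if min(n_a, n_b) < 2:
        warnings.warn("group of size < 2 will fail downstream bootstrap")
    rng = np.random.default_rng(seed)
    return (rng.normal(mean_a, sd, size=n_a), rng.normal(mean_b, sd, size=n_b))
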