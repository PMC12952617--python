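"""Two-state negative-binomial HMM of locomotor activity with periodic,
time-of-day-dependent switching probabilities and individual random
intercepts.

Model
-----
Hidden states j ∈ {1 = inactive, 2 = active}.  Counts in state j follow a
negative binomial with mean ``mu_j`` and dispersion ``phi_j`` (variance
``mu + mu^2/phi``).  The switching probabilities are logit-linear in a
truncated Fourier basis of time of day::

    logit gamma_12(t) = beta0_12 + u_12 + sum_k a_k cos(2 pi k zt/24) + b_k sin(.)
    logit gamma_21(t) = beta0_21 + u_21 + ...

with per-fly random intercepts (u_12, u_21) ~ iid Normal(0, sigma_u^2),
one shared variance for both switching probabilities.  The marginal
likelihood integrates the random effects by Gauss–Hermite quadrature.

Emission parameters are estimated on the control genotype only (with
sigma_u fixed at 0) and then frozen when fitting the other genotypes, so
that the activity states are comparable across genotypes.  LD and DD are
fitted as separate models.

The analysis endpoint is the model-implied probability of the active
state over the 24-h cycle (the periodically stationary distribution of
the inhomogeneous chain), and the between-individual SD of that
probability at the morning and evening activity peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp

from .dam_io import ActivitySeries

__all__ = [
    "NBParams", "HMMSpec", "HMMFit", "OccupancyCurve", "VariabilityStat",
    "nb_logpmf", "transition_matrices", "periodic_stationary",
    "hmm_loglik", "fit_emissions", "fit_hmm",
    "occupancy_curve", "occupancy_sd_at_peaks",
]


class FitError(RuntimeError):
    """Optimizer failed to converge after all restarts."""


@dataclass(frozen=True)
class NBParams:
    """State-dependent negative-binomial emission parameters.

    ``mu`` and ``phi`` are length-2 arrays ordered (inactive, active);
    variance is ``mu + mu^2/phi``.
    """

    mu: np.ndarray
    phi: np.ndarray
    segment: str = "LD"

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))
        if self.mu.shape != (2,) or self.phi.shape != (2,):
            raise ValueError("mu and phi must each hold one value per state")
        if np.any(self.phi <= 0) or np.any(self.mu < 0):
            raise ValueError("phi must be positive and mu non-negative")
        if self.mu[1] < self.mu[0]:
            raise ValueError("state order must satisfy mu_inactive <= mu_active")


@dataclass(frozen=True)
class HMMSpec:
    """Periodic 2-state model specification.

    ``beta12``/``beta21`` hold (beta0, a_1, b_1, ..., a_K, b_K) on the
    logit scale for the inactive→active and active→inactive switching
    probabilities respectively.
    """

    emissions: NBParams
    beta12: np.ndarray
    beta21: np.ndarray
    sigma_u: float = 0.0
    bin_width: int = 30  # minutes
    cycle_length: float = 24.0  # hours

    def __post_init__(self):
        object.__setattr__(self, "beta12", np.asarray(self.beta12, dtype=float))
        object.__setattr__(self, "beta21", np.asarray(self.beta21, dtype=float))
        if self.beta12.shape != self.beta21.shape or self.beta12.ndim != 1:
            raise ValueError("beta12 and beta21 must be 1-D and equally long")
        if (len(self.beta12) - 1) % 2 != 0:
            raise ValueError("coefficient vectors must have odd length 1 + 2K")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be non-negative")

    @property
    def n_harmonics(self) -> int:
        return (len(self.beta12) - 1) // 2

    @property
    def bins_per_cycle(self) -> int:
        return int(round(self.cycle_length * 60 / self.bin_width))

    def cycle_grid(self) -> np.ndarray:
        """zt at each bin start over one cycle."""
        return np.arange(self.bins_per_cycle) * self.bin_width / 60.0


@dataclass
class HMMFit:
    """A fitted model: MLEs, marginal log-likelihood, per-fly intercepts."""

    spec: HMMSpec
    log_likelihood: float
    u_hat: dict[str, np.ndarray]
    converged: bool
    boundary_sigma: bool
    n_flies: int
    seed: int | None = None
    restarts_used: int = 1
    message: str = ""


@dataclass
class OccupancyCurve:
    """Model-implied P(active) over one cycle for a single individual."""

    fly_id: str
    grid: np.ndarray  # zt at bin starts
    p_active: np.ndarray

    def __post_init__(self):
        if not np.allclose(np.clip(self.p_active, 0, 1), self.p_active):
            raise ValueError("p_active must lie in [0, 1]")


@dataclass
class VariabilityStat:
    """Between-fly SD of P(active) at a population activity peak."""

    genotype: str
    segment: str
    peak: str  # "morning" | "evening"
    peak_time: float  # zt hours
    sd_between_flies: float  # percentage points
    n_flies: int


# ---------------------------------------------------------------------------
# building blocks


def nb_logpmf(x, mu, phi):
    """Negative-binomial log pmf, (mean, dispersion) parameterization.

    variance = mu + mu**2 / phi; phi -> inf approaches Poisson.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    mu = np.maximum(mu, 1e-12)
    return (
        gammaln(x + phi) - gammaln(phi) - gammaln(x + 1)
        + phi * np.log(phi / (phi + mu))
        + x * np.log(mu / (phi + mu))
    )


def _harmonic_design(zt: np.ndarray, n_harmonics: int, cycle: float = 24.0) -> np.ndarray:
    """Design matrix [1, cos(2pi zt/24), sin(.), cos(4pi zt/24), ...]."""
    zt = np.asarray(zt, dtype=float)
    cols = [np.ones_like(zt)]
    for k in range(1, n_harmonics + 1):
        ang = 2 * np.pi * k * zt / cycle
        cols.append(np.cos(ang))
        cols.append(np.sin(ang))
    return np.stack(cols, axis=-1)


def transition_matrices(spec: HMMSpec, zt: np.ndarray,
                        u: np.ndarray | None = None) -> np.ndarray:
    """Per-bin 2x2 transition matrices Gamma(t) for given times of day.

    ``u`` optionally holds random intercepts; a leading batch dimension
    of shape (Q, 2) yields output (Q, T, 2, 2).
    """
    X = _harmonic_design(zt, spec.n_harmonics, spec.cycle_length)  # (T, P)
    eta12 = X @ spec.beta12
    eta21 = X @ spec.beta21
    if u is not None:
        u = np.asarray(u, dtype=float)
        if u.ndim == 1:
            eta12 = eta12 + u[0]
            eta21 = eta21 + u[1]
        else:  # (Q, 2) batch
            eta12 = eta12[None, :] + u[:, 0, None]
            eta21 = eta21[None, :] + u[:, 1, None]
    g12 = expit(eta12)
    g21 = expit(eta21)
    out = np.empty(g12.shape + (2, 2))
    out[..., 0, 0] = 1 - g12
    out[..., 0, 1] = g12
    out[..., 1, 0] = g21
    out[..., 1, 1] = 1 - g21
    return out


def periodic_stationary(gammas_cycle: np.ndarray, clip: float = 1e-12) -> np.ndarray:
    """Periodically stationary distribution of a cyclic inhomogeneous chain.

    ``gammas_cycle`` has shape (..., C, 2, 2) where Gamma_k maps bin k to
    bin k+1 (mod C).  Returns delta of shape (..., C, 2) with delta_k the
    left fixed vector of the cycle product starting at bin k.
    """
    g = np.asarray(gammas_cycle, dtype=float)
    C = g.shape[-3]
    batch = g.shape[:-3]
    delta = np.empty(batch + (C, 2))
    # fixed point at bin 0: product M = Gamma_0 Gamma_1 ... Gamma_{C-1}
    M = g[..., 0, :, :]
    for k in range(1, C):
        M = M @ g[..., k, :, :]
    # left eigenvector for eigenvalue 1 of the 2x2 stochastic matrix M:
    # delta proportional to (M[1,0], M[0,1])
    p01 = np.clip(M[..., 0, 1], clip, None)
    p10 = np.clip(M[..., 1, 0], clip, None)
    d0 = np.stack([p10, p01], axis=-1)
    d0 = d0 / d0.sum(axis=-1, keepdims=True)
    delta[..., 0, :] = d0
    for k in range(1, C):
        d0 = np.einsum("...i,...ij->...j", d0, g[..., k - 1, :, :])
        delta[..., k, :] = d0
    return delta


def _zt_bin_index(series: ActivitySeries, spec: HMMSpec) -> np.ndarray:
    if series.zt is None:
        raise ValueError("series must be annotated (zt missing)")
    idx = np.rint(series.zt * 60 / spec.bin_width).astype(int) % spec.bins_per_cycle
    return idx


def _forward_batched(logpem: np.ndarray, ztidx: np.ndarray,
                     gammas: np.ndarray, delta0: np.ndarray) -> np.ndarray:
    """Scaled forward algorithm, batched over flies and quadrature nodes.

    logpem: (F, T, 2) emission log-probabilities (shared across nodes).
    ztidx:  (T,) cycle-bin index per time point.
    gammas: (Q, C, 2, 2) transition matrices per node and cycle bin.
    delta0: (Q, 2) initial distribution per node.
    Returns log-likelihood array of shape (F, Q).
    """
    F, T, _ = logpem.shape
    Q = gammas.shape[0]
    # stabilize emissions per (fly, t) before exponentiation
    m = logpem.max(axis=2)  # (F, T)
    pem = np.exp(logpem - m[:, :, None])  # (F, T, 2), max entry 1
    ll = np.repeat(m.sum(axis=1)[:, None], Q, axis=1)  # (F, Q)
    alpha = delta0[None, :, :] * pem[:, None, 0, :]  # (F, Q, 2)
    c = alpha.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(c[:, :, None] > 0, alpha / np.maximum(c, 1e-300)[:, :, None], 0.0)
        ll += np.where(c > 0, np.log(np.maximum(c, 1e-300)), -np.inf)
    for t in range(1, T):
        G = gammas[:, ztidx[t - 1]]  # (Q, 2, 2)
        alpha = np.einsum("fqi,qij->fqj", alpha, G) * pem[:, None, t, :]
        c = alpha.sum(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(c[:, :, None] > 0,
                             alpha / np.maximum(c, 1e-300)[:, :, None], 0.0)
            ll += np.where(c > 0, np.log(np.maximum(c, 1e-300)), -np.inf)
    return ll


def hmm_loglik(series: ActivitySeries, spec: HMMSpec,
               u: np.ndarray | tuple[float, float] = (0.0, 0.0)) -> float:
    """Conditional log-likelihood of one series given random intercepts.

    Scaled forward recursion with time-varying transition matrices; the
    initial distribution is the periodically stationary distribution at
    the series' first bin.  Returns -inf (with a warning) if the model
    assigns the data zero probability.
    """
    u = np.asarray(u, dtype=float).reshape(1, 2)
    ztidx = _zt_bin_index(series, spec)
    grid = spec.cycle_grid()
    gam = transition_matrices(spec, grid, u)  # (1, C, 2, 2)
    delta = periodic_stationary(gam)  # (1, C, 2)
    delta0 = delta[:, ztidx[0], :]
    logpem = np.stack(
        [nb_logpmf(series.counts, spec.emissions.mu[j], spec.emissions.phi[j])
         for j in range(2)], axis=-1)[None]  # (1, T, 2)
    ll = _forward_batched(logpem, ztidx, gam, delta0)[0, 0]
    if not np.isfinite(ll):
        warnings.warn("likelihood underflow: model assigns zero probability")
    return float(ll)


# ---------------------------------------------------------------------------
# fitting


def _prepare_batch(series_set: list[ActivitySeries], spec: HMMSpec):
    """Validate a shared time base and precompute emission log-probs."""
    ztidx0 = _zt_bin_index(series_set[0], spec)
    counts = np.empty((len(series_set), len(ztidx0)), dtype=float)
    for i, s in enumerate(series_set):
        idx = _zt_bin_index(s, spec)
        if len(idx) != len(ztidx0) or np.any(idx != ztidx0):
            raise ValueError("all series in a fit must share the same zt time base")
        counts[i] = s.counts
    return counts, ztidx0


def _emission_logpem(counts: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    return np.stack(
        [nb_logpmf(counts, mu[j], phi[j]) for j in range(2)], axis=-1)


def _batch_loglik(counts_logpem: np.ndarray, ztidx: np.ndarray, spec: HMMSpec,
                  u_nodes: np.ndarray) -> np.ndarray:
    """(F, Q) conditional log-likelihoods at the given intercept nodes."""
    grid = spec.cycle_grid()
    gam = transition_matrices(spec, grid, u_nodes)
    delta = periodic_stationary(gam)
    delta0 = delta[:, ztidx[0], :]
    return _forward_batched(counts_logpem, ztidx, gam, delta0)


def fit_emissions(control_series: list[ActivitySeries], segment: str,
                  n_harmonics: int = 2, bin_width: int = 30,
                  n_restarts: int = 3, seed: int | None = None,
                  maxiter: int = 500) -> tuple[NBParams, HMMSpec]:
    """Estimate emission parameters on pooled control flies (sigma_u = 0).

    Maximizes the full HMM likelihood over emission and transition
    parameters jointly; labels are ordered so mu_inactive <= mu_active.
    Returns the emission component and the full control spec.
    """
    sub = [_segment_view(s, segment) for s in control_series]
    if len(sub) < 1:
        raise ValueError("no control series supplied")
    spec0 = HMMSpec(
        emissions=NBParams(mu=[0.0, 1.0], phi=[1.0, 1.0], segment=segment),
        beta12=np.zeros(1 + 2 * n_harmonics),
        beta21=np.zeros(1 + 2 * n_harmonics),
        sigma_u=0.0, bin_width=bin_width)
    counts, ztidx = _prepare_batch(sub, spec0)
    pooled = counts.ravel()
    lo = np.quantile(pooled, 0.25)
    hi = max(np.quantile(pooled, 0.9), lo + 1.0)
    P = 1 + 2 * n_harmonics
    rng = np.random.default_rng(seed)
    u0 = np.zeros((1, 2))

    def unpack(theta):
        mu = np.exp(theta[0:2])
        phi = np.exp(theta[2:4])
        beta12 = theta[4:4 + P]
        beta21 = theta[4 + P:4 + 2 * P]
        return mu, phi, beta12, beta21

    def nll(theta):
        # raw (possibly unordered) mu inside the likelihood keeps the
        # surface smooth; label order is applied only when packaging
        mu, phi, beta12, beta21 = unpack(theta)
        logpem = _emission_logpem(counts, mu, phi)
        spec_raw = replace(spec0, beta12=beta12, beta21=beta21)
        ll = _batch_loglik_raw(logpem, ztidx, spec_raw, mu, phi, u0)
        return -float(ll.sum())

    def _batch_loglik_raw(logpem, ztidx_, spec_raw, mu, phi, u_nodes):
        grid = spec_raw.cycle_grid()
        gam = transition_matrices(spec_raw, grid, u_nodes)
        delta = periodic_stationary(gam)
        return _forward_batched(logpem, ztidx_, gam, delta[:, ztidx_[0], :])[:, 0]

    base = np.concatenate([
        [np.log(max(lo, 0.05)), np.log(hi)], [0.0, 0.0],
        [-1.5] + [0.0] * (P - 1), [-1.5] + [0.0] * (P - 1)])
    best = None
    for r in range(n_restarts):
        x0 = base if r == 0 else base + rng.normal(0, 0.3, size=base.shape)
        res = minimize(nll, x0, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("emission fit failed on all restarts")
    mu, phi, beta12, beta21 = unpack(best.x)
    if mu[0] > mu[1]:  # resolve label switching: state 1 = inactive
        mu, phi = mu[::-1].copy(), phi[::-1].copy()
        beta12, beta21 = beta21, beta12
    emissions = NBParams(mu=mu, phi=phi, segment=segment)
    spec = HMMSpec(emissions=emissions, beta12=beta12, beta21=beta21,
                   sigma_u=0.0, bin_width=bin_width)
    return emissions, spec


def _segment_view(series: ActivitySeries, segment: str) -> ActivitySeries:
    """Restrict an annotated series to its LD or DD analysis bins."""
    if series.segment is None:
        raise ValueError("series must be annotated before fitting")
    mask = series.segment == segment
    if not mask.any():
        raise ValueError(f"series {series.fly_id} has no {segment} bins")
    return replace(series, counts=series.counts[mask], zt=series.zt[mask],
                   light=series.light[mask], segment=series.segment[mask])


def fit_hmm(series_set: list[ActivitySeries], emissions: NBParams,
            segment: str | None = None, n_harmonics: int = 2,
            bin_width: int = 30, n_quad: int = 7,
            n_restarts: int = 3, seed: int | None = None,
            maxiter: int = 400, x0: np.ndarray | None = None) -> HMMFit:
    """Fit transition coefficients and sigma_u with emissions frozen.

    The marginal likelihood integrates the two random intercepts by
    (non-adaptive) Gauss–Hermite quadrature with ``n_quad`` nodes per
    dimension.  sigma_u is log-parameterized; a fitted value below 1e-4
    is reported as a boundary fit, not an error.
    """
    if segment is not None:
        series_set = [_segment_view(s, segment) for s in series_set]
    spec0 = HMMSpec(emissions=emissions,
                    beta12=np.zeros(1 + 2 * n_harmonics),
                    beta21=np.zeros(1 + 2 * n_harmonics),
                    sigma_u=0.0, bin_width=bin_width)
    counts, ztidx = _prepare_batch(series_set, spec0)
    logpem = _emission_logpem(counts, emissions.mu, emissions.phi)
    P = 1 + 2 * n_harmonics
    nodes, weights = hermgauss(n_quad)
    xa, xb = np.meshgrid(nodes, nodes, indexing="ij")
    logw = (np.log(weights)[:, None] + np.log(weights)[None, :]).ravel() \
        - np.log(np.pi)
    z = np.stack([xa.ravel(), xb.ravel()], axis=-1) * np.sqrt(2.0)  # (Q, 2)
    rng = np.random.default_rng(seed)

    def nll(theta):
        beta12 = theta[0:P]
        beta21 = theta[P:2 * P]
        sigma = np.exp(theta[2 * P])
        spec = replace(spec0, beta12=beta12, beta21=beta21, sigma_u=sigma)
        ll = _batch_loglik(logpem, ztidx, spec, sigma * z)  # (F, Q)
        marg = logsumexp(ll + logw[None, :], axis=1)
        return -float(marg.sum())

    base = np.concatenate([[-1.5] + [0.0] * (P - 1),
                           [-1.5] + [0.0] * (P - 1), [np.log(0.5)]])
    if x0 is not None:
        base = np.asarray(x0, dtype=float)
    best = None
    used = 0
    for r in range(n_restarts):
        start = base if r == 0 else base + rng.normal(0, 0.25, size=base.shape)
        res = minimize(nll, start, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-9})
        used += 1
        if best is None or res.fun < best.fun:
            best = res
        if best.success and r >= 1:
            break
    if best is None or not np.isfinite(best.fun):
        raise FitError("HMM fit did not converge on any restart")
    theta = best.x.copy()
    best_fun = float(best.fun)
    # the profile in log(sigma) flattens toward the boundary; adopt
    # sigma ~ 0 whenever it fits no worse than the interior optimum
    if np.exp(theta[2 * P]) < 0.5:
        theta_b = theta.copy()
        theta_b[2 * P] = np.log(1e-6)
        fun_b = nll(theta_b)
        if fun_b <= best_fun + 1e-3:
            theta, best_fun = theta_b, fun_b
    sigma_hat = float(np.exp(theta[2 * P]))
    boundary = sigma_hat < 1e-4
    spec = replace(spec0, beta12=theta[0:P], beta21=theta[P:2 * P],
                   sigma_u=sigma_hat)
    u_hat = _posterior_modes(series_set, logpem, ztidx, spec)
    return HMMFit(spec=spec, log_likelihood=-best_fun, u_hat=u_hat,
                  converged=bool(best.success), boundary_sigma=boundary,
                  n_flies=len(series_set), seed=seed, restarts_used=used,
                  message=str(best.message))


def _posterior_modes(series_set, logpem, ztidx, spec: HMMSpec) -> dict[str, np.ndarray]:
    """Per-fly posterior-mode random intercepts at the fitted parameters."""
    out: dict[str, np.ndarray] = {}
    sigma = max(spec.sigma_u, 1e-8)
    for i, s in enumerate(series_set):
        lp = logpem[i:i + 1]

        def neg_post(u):
            ll = _batch_loglik(lp, ztidx, spec, u.reshape(1, 2))[0, 0]
            return -(ll - 0.5 * float(u @ u) / sigma ** 2)

        if spec.sigma_u < 1e-6:
            out[s.fly_id] = np.zeros(2)
            continue
        res = minimize(neg_post, np.zeros(2), method="L-BFGS-B",
                       options={"maxiter": 100})
        out[s.fly_id] = res.x
    return out


# ---------------------------------------------------------------------------
# occupancy


def occupancy_curve(fit: HMMFit, fly_id: str) -> OccupancyCurve:
    """Model-implied P(active) over one cycle using the fly's intercepts.

    Solves the periodically stationary distribution of the cycle of
    per-bin transition matrices.
    """
    if fly_id not in fit.u_hat:
        raise KeyError(f"fly {fly_id!r} not in fit")
    u = fit.u_hat[fly_id]
    grid = fit.spec.cycle_grid()
    gam = transition_matrices(fit.spec, grid, u.reshape(1, 2))
    delta = periodic_stationary(gam)[0]  # (C, 2)
    return OccupancyCurve(fly_id=fly_id, grid=grid, p_active=delta[:, 1])


def population_occupancy(fit: HMMFit) -> tuple[np.ndarray, np.ndarray]:
    """Grid and per-fly matrix (F, C) of occupancy curves for all flies."""
    grid = fit.spec.cycle_grid()
    mat = np.stack([occupancy_curve(fit, fid).p_active for fid in fit.u_hat])
    return grid, mat


def occupancy_sd_at_peaks(curves_by_genotype: dict[str, list[OccupancyCurve]],
                          control_genotype: str,
                          lights_on: float, lights_off: float,
                          segment: str = "LD",
                          window_h: float = 3.0) -> list[VariabilityStat]:
    """Between-fly SD of P(active) at the control-defined M and E peaks.

    Peak times are the argmax of the control genotype's population-mean
    curve within ±``window_h`` of lights-on (morning) and lights-off
    (evening); in DD the same projected transition times are used.
    Returns one stat per (genotype, peak) in percentage points.
    """
    if control_genotype not in curves_by_genotype:
        raise ValueError(f"control genotype {control_genotype!r} missing")
    ctrl = curves_by_genotype[control_genotype]
    if len(ctrl) < 1:
        raise ValueError("control group is empty")
    grid = ctrl[0].grid
    mean_ctrl = np.mean([c.p_active for c in ctrl], axis=0)

    def peak_bin(center: float) -> int:
        d = np.abs((grid - center + 12) % 24 - 12)
        mask = d <= window_h + 1e-9
        cand = np.flatnonzero(mask)
        vals = mean_ctrl[cand]
        if np.allclose(vals, vals[0]):
            warnings.warn("flat control curve in peak window; earliest bin used")
        return int(cand[np.argmax(vals)])

    # in DD, lights_on/off are understood as the projected transitions;
    # zt is referenced to the last actual lights-on so the same zt values apply
    k_m = peak_bin(0.0)
    k_e = peak_bin((lights_off - lights_on) % 24)
    stats: list[VariabilityStat] = []
    for genotype, curves in curves_by_genotype.items():
        if len(curves) < 2:
            raise ValueError(f"genotype {genotype!r} needs >=2 flies")
        mat = np.stack([c.p_active for c in curves])
        for peak, k in (("morning", k_m), ("evening", k_e)):
            stats.append(VariabilityStat(
                genotype=genotype, segment=segment, peak=peak,
                peak_time=float(grid[k]),
                sd_between_flies=float(np.std(mat[:, k], ddof=1) * 100.0),
                n_flies=mat.shape[0]))
    return stats
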