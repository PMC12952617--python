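"""Estimation statistics for two-group comparisons: the mean difference
with a percentile bootstrap 95% confidence interval."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["EffectSize", "bootstrap_mean_diff"]


@dataclass
class EffectSize:
    mean_a: float
    mean_b: float
    difference: float  # mean_b - mean_a
    ci_low: float
    ci_high: float
    n_a: int
    n_b: int
    n_boot: int
    seed: int | None

    def to_dict(self) -> dict:
        return asdict(self)


def bootstrap_mean_diff(a, b, n_boot: int = 5000,
                        seed: int | None = None,
                        ci_level: float = 0.95) -> EffectSize:
    """Mean difference (b - a) with a percentile bootstrap CI.

    Each group is resampled with replacement ``n_boot`` times; the CI is
    the percentile interval of the bootstrap differences.  Deterministic
    under ``seed``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    rng = np.random.default_rng(seed)
    boot_a = rng.choice(a, size=(n_boot, len(a)), replace=True).mean(axis=1)
    boot_b = rng.choice(b, size=(n_boot, len(b)), replace=True).mean(axis=1)
    diffs = boot_b - boot_a
    alpha = (1 - ci_level) / 2
    lo, hi = np.quantile(diffs, [alpha, 1 - alpha])
    return EffectSize(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        difference=float(b.mean() - a.mean()),
        ci_low=float(lo), ci_high=float(hi),
        n_a=len(a), n_b=len(b), n_boot=n_boot, seed=seed)
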