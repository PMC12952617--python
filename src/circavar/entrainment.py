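"""Entrainment Index: the fraction of activity in the 6 h before a light
transition relative to the 12 h flanking it.  A fly whose day-averaged EI
exceeds 0.75 (strictly) at a transition counts as entrained there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dam_io import ActivitySeries, CoverageError, PhotoRegime

__all__ = ["EIResult", "window_sums", "entrainment_index", "fly_ei",
           "percent_entrained", "ei_table"]

ENTRAINMENT_THRESHOLD = 0.75
WINDOW_HOURS = 6.0


@dataclass
class EIResult:
    fly_id: str
    transition: str  # "lights_on" | "lights_off"
    ei: float | None  # None when no activity fell in either window
    before_sum: float
    after_sum: float
    entrained: bool | None
    genotype: str = ""


def _cycle_hours(series: ActivitySeries) -> np.ndarray:
    """Hours since the lights-on that opens LD day 1, per bin."""
    if series.zt is None:
        raise ValueError("series must be annotated")
    offset = series.zt[0] if series.zt[0] <= 12 else series.zt[0] - 24
    return offset + series.times


def window_sums(series: ActivitySeries, transition: str, day: int,
                regime: PhotoRegime,
                startle_correction: bool = False) -> tuple[float, float]:
    """Activity sums in [t-6h, t) and [t, t+6h) around one LD transition.

    ``day`` is the 1-based LD day index.  With ``startle_correction`` the
    first bin at/after the transition (the bin that receives the startle
    burst) is excluded from the after-window sum.
    """
    if transition not in ("lights_on", "lights_off"):
        raise ValueError("transition must be 'lights_on' or 'lights_off'")
    at = (day - 1) * 24.0
    if transition == "lights_off":
        at += regime.photoperiod_hours
    tc = _cycle_hours(series)
    eps = 1e-9
    before = (tc >= at - WINDOW_HOURS - eps) & (tc < at - eps)
    after = (tc >= at - eps) & (tc < at + WINDOW_HOURS - eps)
    expected = int(round(WINDOW_HOURS * 60 / series.bin_width))
    if before.sum() != expected or after.sum() != expected:
        raise CoverageError(
            f"{transition} day {day}: 6-h windows not fully recorded "
            f"({before.sum()}/{after.sum()} of {expected} bins)")
    after_idx = np.flatnonzero(after)
    if startle_correction:
        after_idx = after_idx[1:]
    return float(series.counts[before].sum()), float(series.counts[after_idx].sum())


def entrainment_index(before_sum: float, after_sum: float) -> float | None:
    """EI = before / (before + after); None when both sums are zero."""
    if before_sum < 0 or after_sum < 0:
        raise ValueError("window sums must be non-negative")
    total = before_sum + after_sum
    if total == 0:
        return None
    return before_sum / total


def fly_ei(series: ActivitySeries, transition: str, regime: PhotoRegime,
           days: list[int] | None = None,
           startle_correction: bool = False) -> EIResult:
    """Per-fly EI: daily EIs averaged over the LD analysis days, then
    thresholded (strict > 0.75).

    ``days`` defaults to the last ``ld_analysis_days`` recorded LD days.
    Days whose windows fall outside the recording are skipped; a day with
    zero activity in both windows contributes no EI.
    """
    if days is None:
        days = list(range(regime.n_ld_days - regime.ld_analysis_days + 1,
                          regime.n_ld_days + 1))
    daily, b_tot, a_tot = [], 0.0, 0.0
    for day in days:
        try:
            b, a = window_sums(series, transition, day, regime,
                               startle_correction=startle_correction)
        except CoverageError:
            continue
        b_tot += b
        a_tot += a
        ei_day = entrainment_index(b, a)
        if ei_day is not None:
            daily.append(ei_day)
    if not daily:
        return EIResult(series.fly_id, transition, None, b_tot, a_tot, None,
                        genotype=series.genotype)
    ei = float(np.mean(daily))
    return EIResult(series.fly_id, transition, ei, b_tot, a_tot,
                    ei > ENTRAINMENT_THRESHOLD, genotype=series.genotype)


def percent_entrained(results: list[EIResult]) -> tuple[int, int, float]:
    """(n_entrained, n_with_defined_ei, percentage) for one transition.

    Flies whose EI is undefined (no activity in either window on any
    analysis day) are excluded from the denominator.
    """
    if not results:
        raise ValueError("no EI results supplied")
    defined = [r for r in results if r.ei is not None]
    if not defined:
        raise ValueError("no fly has a defined EI")
    n_ent = sum(1 for r in defined if r.entrained)
    return n_ent, len(defined), 100.0 * n_ent / len(defined)


def ei_table(results: list[EIResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"fly_id": r.fly_id, "genotype": r.genotype,
          "transition": r.transition, "ei": r.ei,
          "before_sum": r.before_sum, "after_sum": r.after_sum,
          "entrained": r.entrained} for r in results])
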