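from datetime import datetime

import numpy as np
import pytest

from circavar.dam_io import ActivitySeries, PhotoRegime
from circavar.phase_circular import (circular_mean, circular_summary,
                                     daily_peak_phase, equal_kappa_pairwise,
                                     fly_phase, kappa_ml, watson_gof)
from circavar.synthetic_data import GenotypeSimParams, simulate_activity


def dd_series(counts, bin_width=30):
    counts = np.asarray(counts)
    n = len(counts)
    zt = (np.arange(n) * bin_width / 60.0) % 24
    return ActivitySeries(fly_id="f", genotype="g", bin_width=bin_width,
                          t0=datetime(2024, 1, 1, 8), counts=counts,
                          light=np.full(n, "D"), zt=zt,
                          segment=np.full(n, "DD"))


class TestDailyPeakPhase:
    def cosine_day(self, peak_zt, days=3, bin_width=30, amp=50):
        n = days * 24 * 60 // bin_width
        zt = (np.arange(n) * bin_width / 60.0) % 24
        counts = np.rint(amp * (1 + np.cos(2 * np.pi * (zt - peak_zt) / 24)))
        return dd_series(counts.astype(int), bin_width)

    def test_peak_at_ct12(self):
        s = self.cosine_day(12.0)
        assert daily_peak_phase(s, 2) == pytest.approx(np.pi, abs=0.14)

    def test_six_hour_shift_is_quarter_turn(self):
        p0 = daily_peak_phase(self.cosine_day(6.0), 2)
        p1 = daily_peak_phase(self.cosine_day(12.0), 2)
        assert (p1 - p0) % (2 * np.pi) == pytest.approx(np.pi / 2, abs=0.14)

    def test_all_zero_day_missing(self):
        s = dd_series(np.zeros(48 * 3, dtype=int))
        assert daily_peak_phase(s, 1) is None

    def test_simulator_phase_recovery(self):
        # flies with a known Von Mises phase offset; evening activity peak
        regime = PhotoRegime(8.0, 20.0, 1, 4, ld_analysis_days=1,
                             dd_analysis_days=4)
        th = 2 * np.pi * 12 / 24
        params = GenotypeSimParams(
            genotype="g", n_flies=100, mu=(0.1, 30.0), phi=(2.0, 8.0),
            beta12=(-6.0, 7.0 * np.cos(th), 7.0 * np.sin(th)),
            beta21=(1.5, -2.0 * np.cos(th), -2.0 * np.sin(th)),
            sigma_u=0.0, kappa_phase=8.0)
        sim = simulate_activity(params, regime, seed=10)
        # occupancy lags the switching-rate peak by a common amount, so
        # compare each fly's phase to its true offset after removing the
        # shared lag
        diffs = []
        for s, true_phase in zip(sim.series_set, sim.true_phases):
            ps = fly_phase(s, days=(2, 3))
            if ps is not None:
                diffs.append(np.angle(np.exp(1j * (ps.phase - true_phase))))
        assert len(diffs) > 80
        lag = circular_mean(np.array(diffs))
        centered = np.abs(np.angle(np.exp(1j * (np.array(diffs) - lag))))
        # two 30-min bins: bout-timing noise in the generating chain keeps
        # single-day peaks from resolving finer than this
        assert np.median(centered) < 2 * np.pi * 1.0 / 24


class TestFlyPhase:
    def make(self, d2_peak, d3_peak):
        n = 4 * 48
        zt = (np.arange(n) * 0.5) % 24
        day = np.arange(n) // 48
        counts = np.zeros(n, dtype=int)
        for d, peak in ((1, d2_peak), (2, d3_peak)):  # DD2 = day index 1
            mask = (day == d) & (np.abs(zt - peak) < 0.25)
            counts[mask] = 100
        return dd_series(counts)

    def test_equal_days(self):
        s = self.make(3.0, 3.0)
        ps = fly_phase(s)
        assert ps.phase == pytest.approx(2 * np.pi * 3 / 24, abs=0.15)

    def test_circular_mean_of_two(self):
        assert circular_mean(np.array([0.0, np.pi / 2])) == \
            pytest.approx(np.pi / 4)

    def test_wraparound(self):
        m = circular_mean(np.array([0.1, 2 * np.pi - 0.1]))
        assert min(m, 2 * np.pi - m) == pytest.approx(0.0, abs=1e-12)

    def test_both_days_missing(self):
        s = dd_series(np.zeros(4 * 48, dtype=int))
        assert fly_phase(s) is None


class TestCircularSummary:
    def test_identical_phases_degenerate(self):
        s = circular_summary(np.full(10, 1.3))
        assert s.rbar == 1.0
        assert s.circ_sd == 0.0
        assert np.isinf(s.coherence)
        assert s.degenerate

    def test_antipodal_pair(self):
        s = circular_summary(np.array([0.5, 0.5 + np.pi]))
        assert s.rbar == pytest.approx(0.0, abs=1e-12)
        assert s.kappa == pytest.approx(0.0, abs=1e-6)

    def test_sd_rbar_identity(self, rng):
        theta = rng.vonmises(1.0, 3.0, size=50)
        s = circular_summary(theta)
        assert s.circ_sd == pytest.approx(np.sqrt(-2 * np.log(s.rbar)))
        assert s.coherence == pytest.approx(1 / s.circ_sd)

    def test_kappa_ml_recovery(self):
        rng = np.random.default_rng(77)
        theta = rng.vonmises(1.0, 2.0, size=500)
        s = circular_summary(theta)
        assert abs(s.kappa - 2.0) / 2.0 < 0.10
        assert abs(np.angle(np.exp(1j * (s.mu - 1.0)))) < 0.1

    def test_rotation_equivariance(self, rng):
        theta = rng.vonmises(0.5, 2.0, size=40)
        rot = 1.234
        s0 = circular_summary(theta)
        s1 = circular_summary((theta + rot) % (2 * np.pi))
        assert s1.rbar == pytest.approx(s0.rbar)
        assert s1.kappa == pytest.approx(s0.kappa, rel=1e-9)
        assert s1.coherence == pytest.approx(s0.coherence)
        assert np.angle(np.exp(1j * (s1.mu - s0.mu - rot))) == \
            pytest.approx(0.0, abs=1e-9)
        assert np.angle(np.exp(1j * (s1.median - s0.median - rot))) == \
            pytest.approx(0.0, abs=1e-9)

    def test_n_below_two_is_error(self):
        with pytest.raises(ValueError):
            circular_summary(np.array([1.0]))

    def test_kappa_ml_inverts_a_ratio(self):
        from scipy.special import i0e, i1e
        for kappa in (0.5, 2.0, 8.0):
            rbar = i1e(kappa) / i0e(kappa)
            assert kappa_ml(rbar) == pytest.approx(kappa, rel=1e-6)


class TestWatson:
    def test_von_mises_sample_not_rejected(self):
        rng = np.random.default_rng(5)
        theta = rng.vonmises(0.0, 2.0, size=100)
        res = watson_gof(theta, n_boot=400, seed=1)
        assert res.p_value > 0.05

    def test_antipodal_mixture_rejected(self):
        rng = np.random.default_rng(6)
        half = rng.vonmises(0.0, 8.0, size=50)
        other = rng.vonmises(np.pi, 8.0, size=50)
        res = watson_gof(np.concatenate([half, other]), n_boot=400, seed=1)
        assert res.p_value < 0.01

    def test_degenerate_sample_flagged(self):
        res = watson_gof(np.full(50, 0.7), n_boot=100, seed=0)
        assert "degenerate" in res.note

    def test_small_n_warns(self):
        rng = np.random.default_rng(7)
        with pytest.warns(UserWarning, match="underpowered"):
            watson_gof(rng.vonmises(0, 2, size=6), n_boot=50, seed=0)


class TestEqualKappa:
    def test_same_group_vs_itself(self, rng):
        theta = rng.vonmises(0.0, 3.0, size=60)
        res = equal_kappa_pairwise({"a": theta, "b": theta.copy()})
        r = res[0]
        assert abs(r.statistic) < 1e-9
        assert r.p_value > 0.999

    def test_power_kappa8_vs_kappa1(self):
        rng = np.random.default_rng(8)
        rejections = 0
        for _ in range(50):
            a = rng.vonmises(0.0, 8.0, size=60)
            b = rng.vonmises(0.0, 1.0, size=60)
            res = equal_kappa_pairwise({"a": a, "b": b})[0]
            rejections += res.p_value < 0.05
        assert rejections >= 45

    def test_small_group_skipped(self, rng):
        groups = {"a": rng.vonmises(0, 2, 60), "b": rng.vonmises(0, 2, 3)}
        res = equal_kappa_pairwise(groups)
        assert "skipped" in res[0].note
        assert np.isnan(res[0].statistic)

    def test_bonferroni(self, rng):
        groups = {g: rng.vonmises(0, 2, 30) for g in "abcd"}
        res = equal_kappa_pairwise(groups)
        tested = [r for r in res if not np.isnan(r.statistic)]
        assert len(tested) == 6
        for r in tested:
            assert r.p_adjusted == pytest.approx(min(1.0, 6 * r.p_value))

    def test_single_group_error(self, rng):
        with pytest.raises(ValueError):
            equal_kappa_pairwise({"a": rng.vonmises(0, 2, 30)})


class TestCoherenceMonotonicity:
    def test_decreasing_kappa_decreases_coherence(self):
        rng = np.random.default_rng(9)
        means = []
        for kappa in (8.0, 4.0, 2.0, 1.0):
            coh = [circular_summary(rng.vonmises(0, kappa, 200)).coherence
                   for _ in range(10)]
            means.append(np.mean(coh))
        assert all(a > b for a, b in zip(means, means[1:]))
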