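"""Downstream statistics: correlation, fits, clustering, comparison,
transition detection."""

import numpy as np
import pytest

from cme import (
    cluster_scatter,
    compare_groups,
    correlate,
    detect_transition,
    find_cme_peaks,
    linear_fit,
    occupancy_ratios,
    theoretical_length_ratio,
)
from cme.exceptions import ConstantSeriesError


class TestCorrelate:
    def test_linear_on_normal_data_uses_pearson(self):
        x = np.random.default_rng(0).standard_normal(100)
        method, coef = correlate(x, 2 * x + 1)
        assert method == "pearson"
        assert coef == pytest.approx(1.0)

    def test_monotone_on_heavy_tails_uses_spearman(self):
        x = np.random.default_rng(1).standard_t(2, 200)
        method, coef = correlate(x, x**3)
        assert method == "spearman"
        assert coef == pytest.approx(1.0)

    def test_independent_data_is_weak(self):
        rng = np.random.default_rng(2)
        _, coef = correlate(rng.standard_normal(200),
                            rng.standard_normal(200))
        assert abs(coef) < 0.2

    def test_constant_series_rejected(self):
        with pytest.raises(ConstantSeriesError):
            correlate(np.ones(10), np.arange(10.0))


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, r2 = linear_fit(x, 0.5 * x + 0.25)
        assert slope == pytest.approx(0.5)
        assert intercept == pytest.approx(0.25)
        assert r2 == pytest.approx(1.0)

    def test_constant_response(self):
        slope, _, r2 = linear_fit(np.arange(5.0), np.ones(5))
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert r2 == 0.0

    def test_noisy_slope_recovered(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 1, 50)
        y = 0.9 * x + rng.normal(0, 0.05, 50)
        slope, _, _ = linear_fit(x, y)
        assert 0.85 <= slope <= 0.95

    def test_constant_x_rejected(self):
        with pytest.raises(ConstantSeriesError):
            linear_fit(np.ones(5), np.arange(5.0))


class TestClusterScatter:
    def _planted(self, rng, sizes=(40, 40, 40)):
        centers = np.array([[0.5, 0.5], [0.62, 0.58], [0.68, 0.58]])
        pts = np.vstack([c + 0.01 * rng.standard_normal((s, 2))
                         for c, s in zip(centers, sizes)])
        truth = np.repeat(np.arange(3), sizes)
        return pts, truth

    def test_recovers_planted_blobs(self):
        pts, truth = self._planted(np.random.default_rng(9))
        cs = cluster_scatter(pts, k=3, seed=9)
        assert (cs.labels == truth).mean() >= 0.95
        # relabeling orders clusters by ascending mean CMEa
        assert np.all(np.diff(cs.means[:, 0]) > 0)

    def test_percentages_sum_to_100(self):
        pts, _ = self._planted(np.random.default_rng(10), sizes=(30, 50, 20))
        cs = cluster_scatter(pts, k=3, seed=0)
        assert cs.percentages.sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_cluster_holds_everything(self):
        pts = np.random.default_rng(1).random((12, 2))
        cs = cluster_scatter(pts, k=1, seed=0)
        assert cs.percentages.tolist() == [100.0]

    def test_deterministic_given_seed(self):
        pts, _ = self._planted(np.random.default_rng(11))
        a = cluster_scatter(pts, k=3, seed=5)
        b = cluster_scatter(pts, k=3, seed=5)
        assert np.array_equal(a.labels, b.labels)

    def test_k_exceeding_distinct_points_rejected(self):
        pts = np.tile([[0.5, 0.5]], (12, 1))
        with pytest.raises(ValueError):
            cluster_scatter(pts, k=3, seed=0)


class TestOccupancyRatios:
    def test_printed_dwell_ratios(self):
        ratios = occupancy_ratios([34.2, 39.5, 26.3])
        assert ratios["I/III"] == 1.3
        assert ratios["II/III"] == 1.5
        assert ratios["I/(II+III)"] == 0.52

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            occupancy_ratios([60.0, 40.0, 0.0])


class TestTheoreticalLengthRatio:
    def test_chamber_channel_array(self):
        assert theoretical_length_ratio(3, 23, 4, 18) == 0.96

    @pytest.mark.parametrize("args", [(1, 7.0, 1, 7.0), (2, 10, 4, 5)])
    def test_equal_totals_give_one(self, args):
        assert theoretical_length_ratio(*args) == 1.0

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            theoretical_length_ratio(0, 23, 4, 18)


class TestCompareGroups:
    def test_large_shift_two_normal_groups(self):
        rng = np.random.default_rng(13)
        res = compare_groups([rng.normal(0, 1, 30), rng.normal(2, 1, 30)])
        assert res.p_value < 0.001
        assert res.stars == "***"
        # the chosen test follows the recorded branch decisions
        parametric = (res.decisions["normal_raw"]
                      and res.decisions["equal_var_raw"])
        assert res.test == ("t-test" if parametric else "Wilcoxon rank sum")

    def test_exponential_null_uses_kruskal_wallis(self):
        # same distribution in all groups: the chosen nonparametric test
        # should stay quiet in the vast majority of repeats
        quiet = 0
        chosen = set()
        rng = np.random.default_rng(14)
        for _ in range(100):
            res = compare_groups([rng.exponential(1, 30) for _ in range(3)])
            chosen.add(res.test)
            quiet += res.p_value > 0.05
        assert "Kruskal-Wallis" in chosen
        assert quiet >= 90

    def test_identical_groups_not_significant(self):
        g = np.random.default_rng(15).normal(0, 1, 20)
        res = compare_groups([g, g.copy()])
        assert res.p_value == pytest.approx(1.0)
        assert res.stars == "n.s."

    def test_acos_transform_only_on_unit_interval_data(self):
        rng = np.random.default_rng(16)
        bounded = [np.clip(rng.beta(0.3, 0.3, 30), 0, 1) for _ in range(2)]
        res = compare_groups(bounded)
        assert isinstance(res.acos_applied, bool)
        unbounded = [rng.exponential(5, 30) + 2 for _ in range(2)]
        res2 = compare_groups(unbounded)
        assert res2.acos_applied is False

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 7.0]])


class TestDetectTransition:
    def test_planted_changepoint_located(self):
        t = np.arange(0, 101, 2.0)
        rng = np.random.default_rng(21)
        y = np.where(t <= 50, 0.5, 0.5 + 0.004 * (t - 50))
        y = y + rng.normal(0, 0.01, t.size)
        rep = detect_transition((t, y))
        assert 40 <= rep.breakpoint_time <= 60
        assert rep.transition
        assert rep.post_slope > rep.pre_slope

    def test_flat_noise_declares_nothing(self):
        t = np.arange(0, 101, 2.0)
        hits = 0
        for s in range(20):
            y = 0.5 + np.random.default_rng(100 + s).normal(0, 0.01, t.size)
            hits += detect_transition((t, y)).transition
        assert hits <= 1

    def test_pure_ramp_has_no_slope_change(self):
        t = np.arange(0, 101, 2.0)
        y = 0.3 + 0.004 * t + np.random.default_rng(3).normal(0, 0.005,
                                                              t.size)
        assert detect_transition((t, y)).transition is False

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_transition((np.arange(5.0), np.zeros(5)))


class TestFindCmePeaks:
    def test_isolated_bumps_found(self):
        y = np.full(40, 0.1)
        for c in (8, 20, 32):
            y[c - 2: c + 3] += 0.3 * np.array([0.3, 0.8, 1.0, 0.8, 0.3])
        peaks = find_cme_peaks(y, prominence=0.1)
        assert sorted(peaks.tolist()) == [8, 20, 32]
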