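"""Displacement histograms, Shannon entropy, and the per-frame CME."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cme import (
    AnalysisConfig,
    BinaryMask,
    DisplacementSeries,
    PMF,
    clean_mask,
    cme_of_boundary,
    cme_series,
    compute_cme,
    extract_boundary,
    find_cme_peaks,
    histogram_pmf,
    normalized_entropy,
    shannon_entropy,
    suggest_lag,
)
from cme.exceptions import CMEError, NoDisplacementsError
from cme.synthetic import (
    SceneSpec,
    ShapeSpec,
    boundary_from_polygon,
    make_mode_masks,
    make_scene,
    make_shape,
    rasterize,
)


def entropy_oracle(p):
    """Independent plain-Python summation of -sum p log2 p."""
    total = 0.0
    for pi in p:
        if pi > 0:
            total -= pi * np.log2(pi)
    return total


class TestHistogramPmf:
    def test_all_equal_values_occupy_one_bin(self):
        pmf = histogram_pmf([3.0] * 10, n_bins=8)
        assert np.sort(pmf.p)[-1] == 1.0
        assert pmf.p.sum() == pytest.approx(1.0, abs=1e-15)

    def test_explicit_range_quarters(self):
        pmf = histogram_pmf([0, 1, 2, 3], n_bins=4, value_range=(0, 4))
        assert pmf.p == pytest.approx([0.25] * 4)

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(7)
        v = rng.standard_normal(1000)
        pmf = histogram_pmf(v, n_bins=16)
        # oracle: explicit counting loop with a closed rightmost bin
        edges = pmf.bin_edges
        counts = np.zeros(16)
        for x in v:
            for i in range(16):
                hi_ok = x <= edges[i + 1] if i == 15 else x < edges[i + 1]
                if edges[i] <= x and hi_ok:
                    counts[i] += 1
                    break
        assert pmf.p == pytest.approx(counts / 1000)
        assert pmf.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(NoDisplacementsError):
            histogram_pmf([], n_bins=4)
        with pytest.raises(ValueError):
            histogram_pmf([0.0, np.nan, 1.0], n_bins=4)


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [([0.5, 0.5], 1.0), ([1.0, 0.0], 0.0), ([0.5, 0.25, 0.25], 1.5)],
    )
    def test_known_values(self, p, expected):
        pmf = PMF(bin_edges=np.arange(len(p) + 1, dtype=float), p=np.array(p))
        assert shannon_entropy(pmf) == pytest.approx(expected)

    def test_matches_independent_oracle_on_random_pmfs(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(2, 40))
            raw = rng.random(n)
            raw[rng.random(n) < 0.3] = 0.0  # exercise the 0 log 0 branch
            if raw.sum() == 0:
                raw[0] = 1.0
            p = raw / raw.sum()
            p[np.argmax(p)] += 1.0 - p.sum()  # force exact unit mass
            pmf = PMF(bin_edges=np.arange(n + 1, dtype=float), p=p)
            assert abs(shannon_entropy(pmf) - entropy_oracle(p)) < 1e-12


class TestNormalizedEntropy:
    def test_uniform_reaches_one(self):
        for n in (2, 5, 16):
            assert normalized_entropy(np.log2(n), n) == pytest.approx(1.0)

    def test_zero_entropy(self):
        assert normalized_entropy(0.0, 16) == 0.0

    def test_direct_evaluation(self):
        assert normalized_entropy(1.5, 3) == pytest.approx(1.5 / np.log2(3))

    def test_requires_two_bins(self):
        with pytest.raises(ValueError):
            normalized_entropy(0.5, 1)


class TestComputeCme:
    def test_analytic_circle_is_exactly_zero(self):
        poly = make_shape(ShapeSpec(family="circle", base_radius=40))
        res = cme_of_boundary(boundary_from_polygon(poly), AnalysisConfig(dN=1))
        assert res.cmea == 0.0
        assert res.cmer == 0.0

    def test_ameboid_below_mesenchymal(self):
        # frozen regression values for the fixed fixtures (seed 1, dN 4)
        cfg = AnalysisConfig(dN=4)
        am = [cme_of_boundary(extract_boundary(clean_mask(m)), cfg)
              for m in make_mode_masks("ameboid", 10, seed=1)]
        me = [cme_of_boundary(extract_boundary(clean_mask(m)), cfg)
              for m in make_mode_masks("mesenchymal", 8, seed=1)]
        am_a = np.mean([r.cmea for r in am])
        me_a = np.mean([r.cmea for r in me])
        assert am_a < me_a
        assert am_a == pytest.approx(0.026195, abs=1e-3)
        assert me_a == pytest.approx(0.334546, abs=1e-3)

    def test_rasterized_disk_stays_below_lattice_ceiling(self):
        # frozen ceiling for pixel-lattice noise of a radius-40 disk
        mask = rasterize(make_shape(ShapeSpec(family="circle",
                                              base_radius=40)), 128)
        res = cme_of_boundary(extract_boundary(clean_mask(mask)),
                              AnalysisConfig(dN=2, n_bins=16))
        assert res.cmea < 0.35
        assert res.cmer < 0.35

    def test_random_series_stay_in_unit_interval(self):
        rng = np.random.default_rng(99)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(500):
                m = int(rng.integers(5, 300))
                ds = DisplacementSeries(
                    dr=rng.normal(0, rng.uniform(0.01, 5), m),
                    dtheta=np.clip(rng.normal(0.05, 0.3, m), -np.pi, np.pi),
                    r_mean=float(rng.uniform(5, 100)),
                    dtheta_step=2 * np.pi / (m + 1),
                )
                res = compute_cme(ds, AnalysisConfig(dN=1))
                assert 0.0 <= res.cmea <= 1.0
                assert 0.0 <= res.cmer <= 1.0
                assert res.cme_avg == pytest.approx(
                    0.5 * (res.cmea + res.cmer))

    def test_short_sample_warns_not_errors(self):
        ds = DisplacementSeries(dr=np.arange(5.0), dtheta=np.arange(5.0) / 10,
                                r_mean=10.0, dtheta_step=0.1)
        with pytest.warns(UserWarning):
            compute_cme(ds, AnalysisConfig(n_bins=16))

    def test_monotone_in_protrusion_amplitude(self):
        cfg = AnalysisConfig(dN=4)
        vals = []
        for amp in np.linspace(0.0, 0.6, 7):
            spec = ShapeSpec(family="protrusive", base_radius=40, n_bumps=2,
                             bump_amplitude=amp, bump_width=0.45,
                             noise_sd=0.01, seed=3)
            mask = rasterize(make_shape(spec), 160)
            vals.append(cme_of_boundary(extract_boundary(clean_mask(mask)),
                                        cfg).cmer)
        diffs = np.diff(vals)
        assert np.all(diffs >= -0.02)  # bin-noise tolerance
        assert vals[-1] > vals[0]      # strict endpoint ordering


class TestCmeSeries:
    def test_identical_disks_give_constant_series(self, disk_mask):
        ts = cme_series([disk_mask] * 10, AnalysisConfig(dN=2))
        assert len(ts.results) == 10
        assert np.ptp(ts.cmea) == 0.0
        assert np.ptp(ts.cmer) == 0.0
        assert all(s == "ok" for s in ts.statuses)

    def test_failed_frame_recorded_not_dropped(self, disk_mask):
        frames = [disk_mask.pixels.astype(float) * 200,
                  np.zeros((100, 100)),
                  disk_mask.pixels.astype(float) * 200]
        ts = cme_series(frames, AnalysisConfig(dN=2))
        assert len(ts.results) == 3
        assert ts.results[1] is None
        assert ts.statuses[1].startswith("failed")
        assert ts.statuses[0] == "ok"
        df = ts.to_frame()
        assert len(df) == 3
        assert df.loc[1, "status"] != "ok"

    def test_all_frames_failing_is_an_error(self):
        with pytest.raises(CMEError):
            cme_series([np.zeros((50, 50))] * 3, AnalysisConfig())

    def test_squeeze_series_shows_one_peak_per_channel(self):
        scene = make_scene(SceneSpec(scenario="squeeze", n_frames=40,
                                     seed=11))
        ts = cme_series(scene.stacks["nucleus"], AnalysisConfig(dN=2),
                        times=scene.times)
        peaks = find_cme_peaks(ts.cmea)
        channels = scene.truth[scene.truth["structure"] == "channel"]
        assert len(peaks) == channels["channel_index"].nunique() == 4
        # each detected peak falls inside a channel interval
        for p in peaks:
            assert scene.truth.loc[p, "structure"] == "channel"

    def test_frame_table_schema(self, disk_mask):
        df = cme_series([disk_mask] * 2, AnalysisConfig()).to_frame()
        assert list(df.columns) == [
            "frame", "time_min", "cmea", "cmer", "cme_avg",
            "h_bits_angular", "h_bits_radial", "n_boundary_points", "dN",
            "n_bins", "aspect_ratio", "status",
        ]


class TestSuggestLag:
    def test_returns_valid_small_lag_for_smooth_shape(self):
        poly = make_shape(ShapeSpec(family="blebby", base_radius=50,
                                    n_bumps=8, bump_amplitude=0.2, seed=4))
        mask = rasterize(poly, 200)
        b = extract_boundary(clean_mask(mask))
        dn = suggest_lag(b, AnalysisConfig())
        assert 1 <= dn <= 12


class TestPmfInvariants:
    @given(st.integers(2, 32), st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=50)
    def test_pmf_sums_to_one(self, n_bins, seed):
        v = np.random.default_rng(seed).normal(0, 2, 64)
        pmf = histogram_pmf(v, n_bins=n_bins)
        assert pmf.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(pmf.p >= 0)
        assert pmf.n == n_bins
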