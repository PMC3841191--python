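"""Fingerprint alignment, diversity, binning and the Raup-Crick null model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from biofilmscape import fingerprints as fp


def make_raw(intensity, standard=None, **kw):
    intensity = np.asarray(intensity, float)
    if standard is None:
        standard = np.zeros_like(intensity)
    return fp.RawProfile(intensity, standard, **kw)


def rc_exact_uniform(n_pool, n_a, n_b, obs):
    """Closed-form Raup-Crick under uniform sampling (hypergeometric null)."""
    ks = np.arange(0, min(n_a, n_b) + 1)
    pmf = hypergeom.pmf(ks, n_pool, n_a, n_b)
    frac = pmf[ks > obs].sum() + 0.5 * pmf[ks == obs].sum()
    return 2.0 * frac - 1.0


class TestAlignment:
    def test_single_linear_segment(self):
        std = fp.SizeStandard([1000.0, 4000.0], [100.0, 400.0])
        assert fp.size_map(std, np.array([250.0]))[0] == pytest.approx(2500.0)

    def test_piecewise_segment_slopes(self):
        # segments: (0,0)-(100,100) slope 1; (100,100)-(200,400) slope 3
        std = fp.SizeStandard([0.0, 100.0, 400.0], [0.0, 100.0, 200.0])
        out = fp.size_map(std, np.array([50.0, 150.0, 250.0]))
        assert out[0] == pytest.approx(50.0)  # first segment
        assert out[1] == pytest.approx(100.0 + 50.0 * 3.0)  # hand-computed
        assert out[2] == pytest.approx(400.0 + 50.0 * 3.0)  # extrapolated

    def test_identity_standard_preserves_profile(self):
        n = 400
        x = np.arange(n, dtype=float)
        intensity = np.exp(-0.5 * ((x - 200.0) / 15.0) ** 2)
        raw = make_raw(intensity)
        std = fp.SizeStandard([50.0, 350.0], [50.0, 350.0])
        grid, dens = fp.align_profile(raw, std, grid=x)
        assert np.abs(dens[5:-5] - intensity[5:-5]).max() < 1e-2

    def test_mass_conserved(self):
        rng = np.random.default_rng(4)
        intensity = rng.gamma(2.0, 1.0, size=500)
        raw = make_raw(intensity)
        std = fp.SizeStandard([10.0, 200.0, 900.0], [0.0, 150.0, 499.0])
        sizes = fp.size_map(std, np.arange(500.0))
        total_in = np.trapezoid(intensity, sizes)
        grid, dens = fp.align_profile(raw, std, n_grid=2000)
        edges = np.concatenate([[grid[0]], 0.5 * (grid[1:] + grid[:-1]), [grid[-1]]])
        total_out = float((dens * np.diff(edges)).sum())
        assert total_out == pytest.approx(total_in, rel=1e-6)

    def test_map_monotone(self):
        std = fp.SizeStandard([10.0, 50.0, 300.0], [5.0, 90.0, 400.0])
        out = fp.size_map(std, np.linspace(-50, 600, 200))
        assert np.all(np.diff(out) > 0)

    def test_too_few_standards(self):
        with pytest.raises(ValueError):
            fp.SizeStandard([100.0], [100.0])

    def test_non_monotone_standard(self):
        with pytest.raises(ValueError):
            fp.SizeStandard([100.0, 200.0], [300.0, 250.0])


class TestNormalization:
    def test_peak_mass_is_one(self):
        x = np.arange(500, dtype=float)
        prof = 2.0 + np.exp(-0.5 * ((x - 250) / 10.0) ** 2)
        out = fp.normalize_profile(x, prof, baseline_window=101)
        assert out.abundance.sum() == pytest.approx(1.0)
        assert out.abundance[:150].sum() < 0.05  # flat baseline removed

    def test_scaling_by_total(self):
        x = np.arange(200, dtype=float)
        vals = np.zeros(200)
        vals[50] = 3.0
        vals[150] = 1.0
        out = fp.normalize_profile(x, vals, baseline_window=0)
        assert out.abundance[50] == pytest.approx(0.75)
        assert out.abundance[150] == pytest.approx(0.25)

    def test_two_peak_area_ratio(self):
        x = np.arange(1000, dtype=float)
        prof = (3.0 * np.exp(-0.5 * ((x - 300) / 20.0) ** 2)
                + 1.0 * np.exp(-0.5 * ((x - 700) / 20.0) ** 2))
        out = fp.normalize_profile(x, prof, baseline_window=201)
        assert out.abundance[x < 500].sum() == pytest.approx(0.75, abs=0.01)

    def test_empty_profile_errors(self):
        with pytest.raises(ValueError):
            fp.normalize_profile(np.arange(100.0), np.zeros(100), baseline_window=0)


class TestSimpson:
    def test_single_point(self):
        assert fp.simpson_diversity(np.array([1.0])).d == 0.0

    def test_uniform_four_points(self):
        res = fp.simpson_diversity(np.full(4, 0.25))
        assert res.d == pytest.approx(math.log(4), abs=1e-12)

    @pytest.mark.parametrize("k", [2, 5, 17, 50, 100])
    def test_uniform_closed_form(self, k):
        res = fp.simpson_diversity(np.full(k, 1.0 / k))
        assert res.d == pytest.approx(math.log(k), rel=1e-10)
        assert res.lam == pytest.approx(1.0 / k, rel=1e-10)

    def test_two_gaussians_direct_sum_oracle(self):
        x = np.linspace(0, 100, 2001)
        prof = (np.exp(-0.5 * ((x - 30) / 3.0) ** 2)
                + np.exp(-0.5 * ((x - 70) / 3.0) ** 2))
        p = prof / prof.sum()
        res = fp.simpson_diversity(p)
        oracle = sum(v * v for v in p)  # independent summation
        assert res.lam == pytest.approx(oracle, abs=1e-9)
        assert res.d == pytest.approx(-math.log(oracle), abs=1e-9)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            fp.simpson_diversity(np.array([0.5, 0.2]))


def gauss_profile(centers, amps, width=2.0, lo=0.0, hi=100.0, n=2000):
    x = np.linspace(lo, hi, n)
    y = np.zeros(n)
    for c, a in zip(centers, amps):
        y += a * np.exp(-0.5 * ((x - c) / width) ** 2)
    y = y / y.sum()
    return fp.FingerprintProfile(grid=x, abundance=y)


class TestDetectPeaks:
    def test_one_gaussian_centered(self):
        prof = gauss_profile([40.0], [1.0])
        pt = fp.detect_peaks(prof, 0.1, 1.0)
        assert len(pt) == 1
        assert pt.positions[0] == pytest.approx(40.0, abs=0.1)
        assert pt.areas[0] == pytest.approx(1.0)

    def test_close_peaks_merge_to_taller(self):
        prof = gauss_profile([50.0, 52.0], [1.0, 0.6], width=1.5)
        pt = fp.detect_peaks(prof, 0.1, min_separation=5.0)
        assert len(pt) == 1
        assert abs(pt.positions[0] - 50.0) < 1.5

    def test_threshold_splits_constructed_fixture(self):
        tall = [10.0, 25.0, 40.0, 60.0, 80.0]
        small = [15.0, 50.0, 90.0]
        prof = gauss_profile(tall + small, [1.0] * 5 + [0.02] * 3, width=1.0)
        pt = fp.detect_peaks(prof, min_height_frac=0.05, min_separation=2.0)
        assert len(pt) == 5

    def test_empty_profile_gives_empty_table(self):
        prof = gauss_profile([50.0], [1.0])
        pt = fp.detect_peaks(prof, min_height_frac=2.0, min_separation=1.0)
        assert len(pt) == 0


def ptable(positions, sample_id, day=0.0, reactor="R"):
    n = len(positions)
    return fp.PeakTable(np.asarray(positions, float), np.full(n, 1.0),
                        np.full(n, 1.0 / n), sample_id, day, reactor)


class TestBinPeaks:
    def test_shared_bin_within_tolerance(self):
        table = fp.bin_peaks([ptable([100.0], "a"), ptable([100.2], "b")], 0.5)
        assert table.n_bins == 1
        assert list(table.occupancy) == [2]

    def test_separate_bins_beyond_tolerance(self):
        table = fp.bin_peaks([ptable([100.0], "a"), ptable([102.0], "b")], 0.5)
        assert table.n_bins == 2

    def test_single_linkage_chaining(self):
        table = fp.bin_peaks([ptable([100.0], "a"), ptable([100.4], "b"),
                              ptable([100.8], "c")], 0.5)
        assert table.n_bins == 1  # documented chaining behaviour

    def test_row_sums_one(self):
        table = fp.bin_peaks([ptable([10.0, 20.0, 30.0], "a"),
                              ptable([10.1, 29.9], "b")], 0.5)
        np.testing.assert_allclose(table.abundance.sum(axis=1), 1.0)

    def test_permutation_invariant_bins(self):
        tables = [ptable([10.0, 50.0], "a"), ptable([10.3, 70.0], "b"),
                  ptable([49.8], "c")]
        t1 = fp.bin_peaks(tables, 0.5)
        t2 = fp.bin_peaks(tables[::-1], 0.5)
        np.testing.assert_allclose(t1.bin_centers, t2.bin_centers)
        assert t1.abundance.sort_index().equals(t2.abundance.sort_index())

    @given(st.floats(0.1, 5.0), st.floats(5.1, 50.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_bin_count_non_increasing_in_tolerance(self, tol_small, tol_big):
        tables = [ptable([10.0, 14.0, 30.0, 55.0], "a"),
                  ptable([11.0, 31.0, 54.0], "b")]
        n_small = fp.bin_peaks(tables, tol_small).n_bins
        n_big = fp.bin_peaks(tables, tol_big).n_bins
        assert n_big <= n_small

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            fp.bin_peaks([ptable([1.0], "a")], 0.0)


class TestRaupCrick:
    def test_full_pool_ties_to_zero(self):
        res = fp.raup_crick([0, 1, 2, 3], [0, 1, 2, 3], np.ones(4),
                            n_reps=999, seed=0)
        assert res.rc == 0.0
        assert not res.significant_similar and not res.significant_dissimilar

    def test_pool_of_four_enumerated_cases(self):
        # uniform pool of 4, richness 2/2: P(SS=0)=1/6, P(1)=4/6, P(2)=1/6
        r_dis = fp.raup_crick([0, 1], [2, 3], np.ones(4), n_reps=99999,
                              weighting="uniform", seed=13)
        r_sim = fp.raup_crick([0, 1], [0, 1], np.ones(4), n_reps=99999,
                              weighting="uniform", seed=13)
        assert r_dis.rc == pytest.approx(5.0 / 6.0, abs=0.01)
        assert r_sim.rc == pytest.approx(-5.0 / 6.0, abs=0.01)

    def test_monte_carlo_matches_enumeration_small_pools(self):
        """Within 3 binomial SE of the exact hypergeometric null, pools <= 6."""
        rng_seed = 0
        for n_pool in range(2, 7):
            for n_a in range(1, n_pool + 1):
                for n_b in range(1, n_pool + 1):
                    obs = max(0, n_a + n_b - n_pool)  # disjoint-as-possible sets
                    a = list(range(n_a))
                    b = list(range(n_pool - n_b, n_pool))
                    n_reps = 20000
                    res = fp.raup_crick(a, b, np.ones(n_pool), n_reps=n_reps,
                                        weighting="uniform", seed=rng_seed)
                    assert res.obs_shared == obs
                    exact = rc_exact_uniform(n_pool, n_a, n_b, obs)
                    ks = np.arange(0, min(n_a, n_b) + 1)
                    pmf = hypergeom.pmf(ks, n_pool, n_a, n_b)
                    q = pmf[ks > obs].sum() + 0.5 * pmf[ks == obs].sum()
                    se = 2.0 * math.sqrt(max(q * (1.0 - q), 0.0) / n_reps)
                    assert abs(res.rc - exact) <= 3.0 * se + 1e-12
                    rng_seed += 1

    def test_symmetric_in_arguments(self):
        occ = np.array([5.0, 3.0, 2.0, 2.0, 1.0])
        r1 = fp.raup_crick([0, 1], [1, 2, 3], occ, n_reps=5001, seed=7)
        r2 = fp.raup_crick([1, 2, 3], [0, 1], occ, n_reps=5001, seed=7)
        assert r1.obs_shared == r2.obs_shared
        assert abs(r1.rc - r2.rc) < 0.05
        assert -1.0 <= r1.rc <= 1.0

    def test_occupancy_weighting_shifts_null(self):
        """Sharing only the commonest species is less surprising under occupancy weights."""
        occ = np.array([50.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        uni = fp.raup_crick([0], [0], np.ones(6), n_reps=20000,
                            weighting="uniform", seed=3)
        wgt = fp.raup_crick([0], [0], occ, n_reps=20000,
                            weighting="occupancy", seed=3)
        assert wgt.rc > uni.rc  # common-species overlap explained by the null

    def test_richness_exceeding_pool(self):
        with pytest.raises(ValueError):
            fp.raup_crick([0, 1, 2], [0], np.ones(2), n_reps=9)


class TestRaupCrickSeries:
    def _table(self, rows, days, reactor="R1"):
        import pandas as pd

        ids = [f"{reactor}_{d}" for d in days]
        abund = pd.DataFrame(rows, index=ids)
        occ = (abund > 0).sum(axis=0).to_numpy()
        meta = pd.DataFrame({"sample_id": ids, "day": days,
                             "reactor": [reactor] * len(days)})
        return fp.CommunityTable(abund, np.arange(abund.shape[1], dtype=float),
                                 occ, meta)

    def test_three_samples_two_comparisons(self):
        t = self._table(np.eye(3) * 0.5 + 0.5 / 3, [1.0, 2.0, 3.0])
        out = fp.raup_crick_series(t, n_reps=99, seed=0)
        assert len(out) == 2
        assert list(out.day_start) == [1.0, 2.0]

    def test_identical_samples_large_pool_significant(self):
        """Consecutive samples sharing a mid-richness presence set from a large
        pool are significantly more similar than random assemblies."""
        pool = 20
        row = np.zeros(pool)
        row[:8] = 1.0 / 8
        rows = [row, row, np.full(pool, 1.0 / pool)]  # third sample fills pool
        t = self._table(rows, [1.0, 2.0, 3.0])
        out = fp.raup_crick_series(t, n_reps=4999, seed=1)
        first = out.iloc[0]
        assert first.obs_shared == 8
        assert first.rc < -0.95
        assert bool(first.significant_similar)

    def test_pairs_follow_day_order_not_input_order(self):
        rows = np.eye(3) * 0.5 + 0.5 / 3
        t = self._table(rows, [5.0, 1.0, 3.0])
        t.meta = t.meta  # days deliberately shuffled relative to rows
        out = fp.raup_crick_series(t, n_reps=99, seed=0)
        assert list(out.day_start) == [1.0, 3.0]
        assert list(out.day_end) == [3.0, 5.0]

    def test_single_sample_reactor_skipped(self, caplog):
        t = self._table([[0.5, 0.5]], [1.0])
        out = fp.raup_crick_series(t, n_reps=9, seed=0)
        assert out.empty
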