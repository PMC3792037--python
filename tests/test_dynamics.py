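"""Cross-correlation decay statistic: tiling, curves, fits, selection, test."""

import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tipkit import dynamics as dyn
from tipkit import synthetic as syn
from tipkit.movie import Movie


def _movie(frames, ps=0.2, dt=1.0):
    return Movie(np.asarray(frames, float), ps, dt)


class TestTileGrid:
    def test_60_micron_frame_yields_181_tiles(self):
        movie = _movie(np.zeros((3, 300, 300)))   # 60×60 µm at 0.2 µm/px
        grid = dyn.tile_movie(movie, 6.0, 3.0)
        assert grid.n_tiles == 100 + 81

    def test_frame_of_exactly_one_tile(self):
        movie = _movie(np.zeros((3, 30, 30)))
        grid = dyn.tile_movie(movie, 6.0, 3.0)
        assert grid.n_tiles == 1

    def test_zero_offset_deduplicates(self):
        movie = _movie(np.zeros((3, 60, 60)))
        assert dyn.tile_movie(movie, 6.0, 0.0).n_tiles == 4

    def test_tile_larger_than_frame(self):
        with pytest.raises(ValueError, match="larger"):
            dyn.tile_movie(_movie(np.zeros((3, 20, 20))), 6.0, 3.0)

    def test_non_integer_conversion_rounds_within_half_pixel(self):
        movie = _movie(np.zeros((3, 100, 100)), ps=0.35)
        grid = dyn.tile_movie(movie, 6.0, 3.0)
        assert grid.size_px == 17        # 6/0.35 = 17.14 -> 17 (|err| < 0.5 px)


class TestXCorrCurve:
    def test_identical_frames_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 100, (16, 16))
        curve = dyn.xcorr_curve(np.repeat(frame[None], 10, axis=0))
        assert np.allclose(curve.y, 1.0)

    def test_iid_noise_near_zero(self):
        rng = np.random.default_rng(1)
        stack = rng.normal(100, 10, (30, 32, 32))
        curve = dyn.xcorr_curve(stack)
        assert np.all(np.abs(curve.y) < 3 / 32)

    def test_ar1_closed_form(self):
        """y(5) ~ 0.3 + 0.7*0.9^5 = 0.7133 for rho=0.9, lam=0.3."""
        ys = []
        for seed in range(8):
            gt = syn.GroundTruth(ar1_rho=0.9, static_fraction=0.3, seed=seed)
            movie, _ = syn.make_ar1_texture_movie(gt, 120, 64)
            curve = dyn.xcorr_curve(movie.frames)
            ys.append(curve.y[4])
        assert np.mean(ys) == pytest.approx(0.3 + 0.7 * 0.9**5, abs=0.02)

    def test_pair_count_bookkeeping(self):
        """sum over intervals of pair counts = T(T-1)/2 at full depth."""
        T = 17
        stack = np.random.default_rng(2).uniform(0, 1, (T, 8, 8))
        curve = dyn.xcorr_curve(stack, max_interval=T - 1)
        assert curve.n_pairs.sum() == T * (T - 1) // 2

    @given(a=st.floats(0.1, 10), b=st.floats(-50, 50))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(3)
        stack = rng.uniform(10, 90, (12, 10, 10))
        y0 = dyn.xcorr_curve(stack).y
        y1 = dyn.xcorr_curve(a * stack + b).y
        assert np.allclose(y0, y1, atol=1e-9)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            dyn.xcorr_curve(np.zeros((2, 8, 8)))


class TestFitDecay:
    def test_exact_model_recovered(self):
        x = np.arange(1.0, 61.0)
        y = (1.0 - 0.3) * np.exp(-0.1 * x) + 0.3
        fit = dyn.fit_decay(dyn.XCorrCurve(x, y, np.ones_like(x), 1.0))
        assert fit.converged
        assert (fit.y0, fit.plateau, fit.K) == pytest.approx((1.0, 0.3, 0.1), abs=1e-6)
        assert fit.span == pytest.approx(0.7, abs=1e-6)

    def test_ar1_k_matches_minus_log_rho(self):
        ks = []
        for seed in range(10):
            gt = syn.GroundTruth(ar1_rho=0.9, static_fraction=0.0, seed=seed)
            movie, _ = syn.make_ar1_texture_movie(gt, 120, 64)
            ks.append(dyn.fit_decay(dyn.xcorr_curve(movie.frames)).K)
        se = np.std(ks, ddof=1) / math.sqrt(len(ks))
        assert abs(np.mean(ks) - (-math.log(0.9))) < 3 * se + 1e-3

    def test_monotone_in_rho(self):
        """Faster texture decorrelation (smaller rho) -> larger fitted K."""
        ks = []
        for rho in [0.95, 0.9, 0.8]:
            gt = syn.GroundTruth(ar1_rho=rho, static_fraction=0.0, seed=0)
            movie, _ = syn.make_ar1_texture_movie(gt, 120, 64)
            ks.append(dyn.fit_decay(dyn.xcorr_curve(movie.frames)).K)
        assert ks[0] < ks[1] < ks[2]

    def test_constant_curve_degenerate(self):
        x = np.arange(1.0, 31.0)
        fit = dyn.fit_decay(dyn.XCorrCurve(x, np.full_like(x, 0.8), np.ones_like(x), 1.0))
        if fit.converged:
            assert abs(fit.span) < 1e-6


class TestSelection:
    def _fits(self, spans, origins=None):
        out = []
        for i, s in enumerate(spans):
            f = dyn.DecayFit(1.0, 1.0 - s, 0.1, s, True, 0.0)
            f.origin_px = origins[i] if origins else (i, 0)
            out.append(f)
        return out

    def test_top_ten_of_twelve(self):
        spans = [round(0.1 * k, 3) for k in range(1, 13)]
        act = dyn.select_top_span(self._fits(spans), 10)
        assert sorted(f.span for f in act.selected) == pytest.approx(spans[2:])

    def test_fewer_than_n_warns_and_keeps_all(self):
        with pytest.warns(UserWarning, match="only 7"):
            act = dyn.select_top_span(self._fits([0.1 * k for k in range(1, 8)]), 10)
        assert len(act.selected) == 7

    def test_tie_break_by_origin(self):
        spans = [0.5] * 12
        origins = [(r, c) for r in range(4) for c in range(3)]
        act = dyn.select_top_span(self._fits(spans, origins), 10)
        assert [f.origin_px for f in act.selected] == sorted(origins)[:10]

    def test_no_converged_fits_raises(self):
        bad = [dyn.DecayFit(np.nan, np.nan, np.nan, np.nan, False, np.nan)]
        with pytest.raises(ValueError, match="no converged"):
            dyn.select_top_span(bad, 10)


class TestCompareActivity:
    def test_identical_groups_p_maximal(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = dyn.compare_activity([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_exact_enumeration_example(self):
        u, p = dyn.compare_activity([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_fast_vs_slow_cohorts_separate(self):
        """rho 0.85 vs 0.95, 15 cells each -> rank-sum p < 0.01."""
        groups = {}
        for rho, base in [(0.85, 100), (0.95, 200)]:
            ks = []
            for seed in range(15):
                gt = syn.GroundTruth(ar1_rho=rho, static_fraction=0.2, seed=base + seed)
                movie, _ = syn.make_ar1_texture_movie(gt, 120, 32)
                ks.append(dyn.fit_decay(dyn.xcorr_curve(movie.frames)).K)
            groups[rho] = ks
        _, p = dyn.compare_activity(groups[0.85], groups[0.95])
        assert p < 0.01

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            dyn.compare_activity([1, 2], [3, 4, 5])


class TestActivityMap:
    def _uniform_cell(self, k=0.1, span=0.5, shape=(60, 60)):
        fits = []
        for r in range(0, 31, 30):
            for c in range(0, 31, 30):
                f = dyn.DecayFit(1.0, 1.0 - span, k, span, True, 0.0)
                f.origin_px = (r, c)
                fits.append(f)
        grid = dyn.TileGrid(6.0, 3.0, 30, np.array([f.origin_px for f in fits]), 0.2)
        return grid, dyn.CellActivity(fits, fits[:1], k)

    def test_uniform_k_uniform_hue(self):
        grid, act = self._uniform_cell()
        rgb = dyn.activity_map(grid, act, (60, 60), k_range=(0.0, 0.2))
        inner = rgb[8:22, 8:22].reshape(-1, 3)
        assert np.allclose(inner, inner[0])

    def test_zero_span_is_black(self):
        grid, act = self._uniform_cell(span=0.0)
        rgb = dyn.activity_map(grid, act, (60, 60), k_range=(0.0, 0.2))
        assert np.allclose(rgb[8:22, 8:22], 0.0)

    def test_two_region_movie_hue_differs(self):
        """Fast left half vs slow right half -> different hues."""
        left = syn.make_ar1_texture_movie(
            syn.GroundTruth(ar1_rho=0.7, seed=0), 60, 60)[0].frames
        right = syn.make_ar1_texture_movie(
            syn.GroundTruth(ar1_rho=0.98, seed=1), 60, 60)[0].frames
        movie = _movie(np.concatenate([left, right], axis=2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            act, grid = dyn.analyze_cell(movie)
        rgb = dyn.activity_map(grid, act, movie.frames.shape[1:])
        import matplotlib.colors as mcolors

        # sample the painted centres of a tile in each half (tiles paint
        # their central region; q = size/4 inset from the tile origin)
        hsv_l = mcolors.rgb_to_hsv(rgb[10:20, 10:20].reshape(-1, 3))
        hsv_r = mcolors.rgb_to_hsv(rgb[10:20, 100:110].reshape(-1, 3))
        lit_l = hsv_l[hsv_l[:, 2] > 0]
        lit_r = hsv_r[hsv_r[:, 2] > 0]
        assert len(lit_l) and len(lit_r)
        assert abs(lit_l[:, 0].mean() - lit_r[:, 0].mean()) > 0.1
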