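"""Axial profiles, peak distances, ratio landmarks, kymographs, tip windows."""

import numpy as np
import pytest

from tipkit import profiles as prof
from tipkit import synthetic as syn
from tipkit import tracking as trk


def _make_profile(values, ps=0.2):
    values = np.asarray(values, float)
    d = (np.arange(len(values)) + 0.5) * ps
    return prof.AxialProfile(d, values[None], values, 1)


class TestAxialProfile:
    def test_uniform_tube_flat_beyond_dome(self):
        gt = syn.GroundTruth(v0=0.5, frame_interval=5.0, noise_sd=0.0,
                             peak_distances=[], baseline=1.0)
        movie, _ = syn.make_growing_hair_movie(gt, 120, "fluorescence")
        ap = prof.axial_profile(movie, trk.track_tip(movie), 10.0)
        shank = ap.mean_profile[ap.distances_um > gt.tube_width_um / 2]
        assert np.nanmin(shank) > 93.0

    def test_per_frame_normalization_max_is_100(self, apical_fluor, apical_fluor_track):
        movie, _ = apical_fluor
        ap = prof.axial_profile(movie, apical_fluor_track, 12.0)
        assert np.allclose(np.nanmax(ap.per_frame, axis=1), 100.0)

    def test_gaussian_component_peak_recovered(self, apical_fluor, apical_fluor_track):
        movie, gt = apical_fluor
        ap = prof.axial_profile(movie, apical_fluor_track, 12.0)
        peak, tie = prof.peak_distance(ap)
        assert not tie
        assert peak == pytest.approx(2.0, abs=0.3)

    def test_two_equal_components_two_local_maxima(self):
        gt = syn.GroundTruth(v0=0.5, frame_interval=5.0, noise_sd=0.0,
                             peak_distances=[(2.0, 1.0, 1.0), (7.0, 1.0, 1.0)])
        movie, _ = syn.make_growing_hair_movie(gt, 120, "fluorescence")
        ap = prof.axial_profile(movie, trk.track_tip(movie), 12.0)
        m = ap.mean_profile
        maxima = [
            ap.distances_um[i]
            for i in range(1, len(m) - 1)
            if m[i] >= m[i - 1] and m[i] >= m[i + 1] and m[i] > 60
        ]
        assert len(maxima) == 2
        assert maxima[0] == pytest.approx(2.0, abs=0.4)
        assert maxima[1] == pytest.approx(7.0, abs=0.4)


class TestPeakDistance:
    def test_unique_max_at_bin_25(self):
        values = np.zeros(60)
        values[25] = 100.0
        peak, tie = prof.peak_distance(_make_profile(values))
        assert peak == pytest.approx(25.5 * 0.2)
        assert not tie

    def test_monotone_decreasing_peaks_at_apex(self):
        peak, _ = prof.peak_distance(_make_profile(np.linspace(100, 10, 50)))
        assert peak == pytest.approx(0.1)

    def test_plateau_tie_resolves_to_centroid_with_flag(self):
        values = np.zeros(20)
        values[4:7] = 100.0
        peak, tie = prof.peak_distance(_make_profile(values))
        assert tie
        assert peak == pytest.approx(5.5 * 0.2)


class TestRatioLandmarks:
    def test_equal_gaussians_cross_midway(self):
        d = (np.arange(60) + 0.5) * 0.2
        a = 100 * np.exp(-((d - 2.0) ** 2) / 2.0)
        b = 100 * np.exp(-((d - 5.0) ** 2) / 2.0)
        crossing, _ = prof.ratio_landmarks(_make_profile(a), _make_profile(b))
        assert crossing == pytest.approx(3.5, abs=0.05)

    def test_identical_profiles_flagged_missing(self):
        a = np.linspace(100, 10, 30)
        crossing, extremal = prof.ratio_landmarks(_make_profile(a), _make_profile(a.copy()))
        assert crossing is None

    def test_apically_peaked_ratio_max_near_apex(self):
        d = (np.arange(60) + 0.5) * 0.2
        a = 100 * np.exp(-((d - 5.0) ** 2) / 8.0)
        b = 100 * np.exp(-((d - 1.0) ** 2) / 8.0)
        _, extremal = prof.ratio_landmarks(_make_profile(a), _make_profile(b))
        assert extremal < 2.0

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            prof.ratio_landmarks(_make_profile(np.ones(10)), _make_profile(np.ones(12)))


class TestKymograph:
    def test_static_tube_tip_line_vertical(self, static_dic):
        movie, _ = static_dic
        track = trk.track_tip(movie)
        _, _, tip_s = prof.kymograph(movie, track)
        v = np.isfinite(tip_s)
        assert np.ptp(tip_s[v]) <= 2 * movie.pixel_size

    def test_growing_tube_slope_matches_growth_rate(self, wt_dic, wt_dic_track):
        movie, _ = wt_dic
        _, _, tip_s = prof.kymograph(movie, wt_dic_track)
        v = np.isfinite(tip_s)
        t = np.arange(len(tip_s))[v] * movie.frame_interval
        slope = np.polyfit(t, tip_s[v], 1)[0] * 60.0
        gs = trk.growth_series(wt_dic_track)
        assert slope == pytest.approx(gs.mean_rate, rel=0.02)

    def test_growth_arrest_changes_slope(self):
        """Piecewise movie: growth for half the movie, then stop."""
        gt1 = syn.GroundTruth(v0=1.5, noise_sd=0.0, frame_shape=(60, 220))
        m1, gt1 = syn.make_growing_hair_movie(gt1, 600, "dic_like")
        gt2 = syn.GroundTruth(v0=0.0, noise_sd=0.0, frame_shape=(60, 220),
                              initial_length_um=10 + gt1.displacement_um(600))
        m2, _ = syn.make_growing_hair_movie(gt2, 600, "dic_like")
        from tipkit.movie import Movie

        movie = Movie(np.concatenate([m1.frames, m2.frames[1:]]), 0.2, 30.0)
        track = trk.track_tip(movie)
        _, _, tip_s = prof.kymograph(movie, track)
        first = np.nanmax(tip_s[:21]) - np.nanmin(tip_s[:21])
        second = np.nanmax(tip_s[21:]) - np.nanmin(tip_s[21:])
        assert first > 10 * max(second, 0.1)


class TestTipWindow:
    def test_uniform_tube_constant_series(self):
        gt = syn.GroundTruth(v0=0.5, frame_interval=5.0, noise_sd=0.0,
                             peak_distances=[], baseline=1.0)
        movie, _ = syn.make_growing_hair_movie(gt, 120, "fluorescence")
        tw = prof.tip_window_intensity(movie, trk.track_tip(movie))
        v = np.isfinite(tw)
        # the discrete pixel set inside the 2 µm window changes as the tip
        # crosses pixel boundaries; allow that rasterization wobble
        assert np.ptp(tw[v]) / np.mean(tw[v]) < 0.12

    def test_fading_apical_signal_decreasing_trend(self, apical_fluor, apical_fluor_track):
        movie, _ = apical_fluor
        tw = prof.tip_window_intensity(movie, apical_fluor_track)
        v = np.isfinite(tw)
        assert tw[v][-1] < tw[v][0]        # bleaching dominates
        from scipy.stats import spearmanr

        rho, _ = spearmanr(np.arange(v.sum()), tw[v])
        assert rho < -0.9

    def test_zero_depth_rejected(self, apical_fluor, apical_fluor_track):
        movie, _ = apical_fluor
        with pytest.raises(ValueError, match="depth"):
            prof.tip_window_intensity(movie, apical_fluor_track, depth_um=0.0)
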