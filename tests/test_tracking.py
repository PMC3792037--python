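"""Tip tracking, growth kinetics and ROI geometry against generator truth."""

import numpy as np
import pytest

from tipkit import synthetic as syn
from tipkit import tracking as trk
from tipkit.movie import Movie


class TestTrackTip:
    def test_static_tube_apex_constant_within_one_pixel(self, static_dic):
        movie, gt = static_dic
        track = trk.track_tip(movie)
        err = np.linalg.norm(track.apex_um - gt.tip_positions_um, axis=1)
        assert track.valid.all()
        assert err.max() <= 1.5 * movie.pixel_size
        spread = np.ptp(track.apex_um[:, 1])
        assert spread <= movie.pixel_size

    def test_growing_tube_tracks_true_displacement(self, wt_dic, wt_dic_track):
        movie, gt = wt_dic
        v = wt_dic_track.valid
        axial = (wt_dic_track.apex_um[v] - gt.tip_positions_um[v]) @ gt.axis_unit
        assert abs(axial.mean()) < 0.25          # small constant bias allowed
        assert axial.std() < 0.15                # jitter well under a pixel

    def test_fluorescence_mode_tracks_subpixel(self, apical_fluor, apical_fluor_track):
        movie, gt = apical_fluor
        v = apical_fluor_track.valid
        err = np.linalg.norm(apical_fluor_track.apex_um[v] - gt.tip_positions_um[v], axis=1)
        assert err.max() <= 1.0 * movie.pixel_size

    def test_blank_movie_hard_error(self):
        blank = Movie(np.zeros((5, 40, 60)), 0.2, 30.0)
        with pytest.raises(ValueError, match="track failed"):
            trk.track_tip(blank)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            trk.track_tip(Movie(np.zeros((1, 40, 60)), 0.2, 30.0))

    def test_axis_is_unit_and_points_to_base(self, wt_dic_track):
        v = wt_dic_track.valid
        norms = np.linalg.norm(wt_dic_track.axis[v], axis=1)
        assert np.allclose(norms, 1.0)
        # hair enters from the left: base direction has negative col component
        assert (wt_dic_track.axis[v][:, 1] < 0).all()


class TestGrowthSeries:
    def test_constant_apex_all_rates_zero_cessation_at_start(self, static_dic):
        movie, _ = static_dic
        track = trk.track_tip(movie)
        gs = trk.growth_series(track)
        assert np.allclose(gs.rate_um_per_min, 0.0, atol=0.2)
        assert gs.cessation_time_s == 0.0

    def test_constant_rate_recovered_within_two_percent(self, wt_dic_track):
        gs = trk.growth_series(wt_dic_track)
        assert gs.mean_rate == pytest.approx(1.26, rel=0.02)

    def test_rate_recovery_sweep(self):
        """Mean-rate recovery within 2% across physiological rates at SNR 10."""
        for v0 in [0.5, 1.0, 2.0]:
            gt = syn.GroundTruth(v0=v0, noise_sd=5.0, seed=int(v0 * 10))
            movie, _ = syn.make_growing_hair_movie(gt, 1200, "dic_like")
            gs = trk.growth_series(trk.track_tip(movie))
            assert gs.mean_rate == pytest.approx(v0, rel=0.02), v0

    def test_interval_consistency(self, wt_dic_track):
        """Mean rate at 30 s and at 60 s intervals agree on the same track."""
        g30 = trk.growth_series(wt_dic_track, 30.0)
        g60 = trk.growth_series(wt_dic_track, 60.0)
        assert g30.mean_rate == pytest.approx(g60.mean_rate, rel=0.02)

    def test_incommensurate_interval_rejected(self, wt_dic_track):
        with pytest.raises(ValueError, match="multiple"):
            trk.growth_series(wt_dic_track, 45.0)

    def test_oscillatory_max_rate(self):
        """Printed-peak recovery: v0(1+a) = 2.33 µm/min within 5%."""
        gt = syn.preset("osc", seed=3)
        movie, _ = syn.make_growing_hair_movie(gt, 900, "dic_like")
        gs = trk.growth_series(trk.track_tip(movie))
        assert gs.max_rate == pytest.approx(2.33, rel=0.05)


class TestROIs:
    def test_apical_roi_center_geometry(self):
        """Apex at (10,10) µm, axis base-ward +x: radius-2 circle at (12,10)."""
        apex = np.array([[10.0, 10.0]])
        axis = np.array([[1.0, 0.0]])
        track = trk.TipTrack(
            apex_um=apex, apex_smooth_um=apex.copy(), axis=axis,
            valid=np.array([True]), masks=np.ones((1, 100, 100), bool),
            pixel_size=0.2, frame_interval=5.0,
        )
        roi = trk.apical_roi(track, 2.0)
        assert roi.circle_centers_um[0] == pytest.approx([12.0, 10.0])

    def test_apical_roi_static_tube_identical_every_frame(self, static_dic):
        movie, _ = static_dic
        roi = trk.apical_roi(trk.track_tip(movie), 2.0)
        assert np.allclose(roi.circle_centers_um, roi.circle_centers_um[0], atol=0.25)

    def test_apical_roi_center_advances_at_growth_rate(self, wt_dic, wt_dic_track):
        movie, gt = wt_dic
        roi = trk.apical_roi(wt_dic_track, 2.0)
        v = np.nonzero(wt_dic_track.valid)[0]
        disp = (roi.circle_centers_um[v[-1]] - roi.circle_centers_um[v[0]]) @ gt.axis_unit
        expected = (gt.tip_positions_um[v[-1]] - gt.tip_positions_um[v[0]]) @ gt.axis_unit
        assert disp == pytest.approx(expected, rel=0.05)

    def test_invalid_radius(self, wt_dic_track):
        with pytest.raises(ValueError):
            trk.apical_roi(wt_dic_track, 0.0)


class TestPMCSROIs:
    @pytest.fixture(scope="class")
    def ring_rois(self):
        gt = syn.GroundTruth(v0=0.3, frame_interval=5.0, pm_cs_ratio=2.0, noise_sd=0.0)
        movie, gt = syn.make_pm_cs_movie(gt, 180)
        track = trk.track_tip(movie)
        return movie, gt, track, trk.pm_cs_rois(track, movie)

    def test_pm_line_spans_central_half(self, ring_rois):
        """Width-8 tube: PM arc transverse extent ~4 µm (central half)."""
        movie, gt, track, rois = ring_rois
        t = np.nonzero(rois.valid)[0][0]
        pts = rois.pm_points_um[t]
        normal = np.array([-track.axis[t][1], track.axis[t][0]])
        extent = np.ptp(pts @ normal)
        assert extent == pytest.approx(gt.tube_width_um / 2.0, abs=0.5)

    def test_cs_line_half_micron_behind(self, ring_rois):
        movie, gt, track, rois = ring_rois
        t = np.nonzero(rois.valid)[0][0]
        gaps = np.linalg.norm(rois.pm_points_um[t] - rois.cs_points_um[t], axis=1)
        assert np.allclose(gaps, 0.5, atol=1e-9)

    def test_cs_line_samples_interior_only(self, ring_rois):
        """On a ratio-2 movie the cytosol line must read the interior level."""
        movie, gt, track, rois = ring_rois
        from tipkit.movie import bilinear_sample

        t = np.nonzero(rois.valid)[0][0]
        vals = bilinear_sample(movie.frames[t], rois.cs_points_um[t] / movie.pixel_size - 0.5)
        assert np.all(np.abs(vals - 100.0) < 10.0)

    def test_hair_width_estimate(self, ring_rois):
        movie, gt, track, rois = ring_rois
        assert rois.meta["hair_width_um"] == pytest.approx(gt.tube_width_um, abs=0.5)
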