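"""Shared fixtures: small synthetic movies reused across test modules."""

import numpy as np
import pytest

from tipkit import synthetic as syn
from tipkit import tracking as trk


@pytest.fixture(scope="session")
def static_dic():
    gt = syn.GroundTruth(v0=0.0, noise_sd=0.0, frame_shape=(80, 140), initial_length_um=15)
    movie, gt = syn.make_growing_hair_movie(gt, 120, "dic_like")
    return movie, gt


@pytest.fixture(scope="session")
def wt_dic():
    """Constant 1.26 µm/min DIC movie, 30 s frames, mild noise."""
    gt = syn.GroundTruth(v0=1.26, noise_sd=5.0, seed=1)
    movie, gt = syn.make_growing_hair_movie(gt, 1500, "dic_like")
    return movie, gt


@pytest.fixture(scope="session")
def wt_dic_track(wt_dic):
    movie, gt = wt_dic
    return trk.track_tip(movie)


@pytest.fixture(scope="session")
def apical_fluor():
    """Fluorescence movie with one Gaussian component 2 µm behind the apex."""
    gt = syn.GroundTruth(
        v0=1.0, frame_interval=5.0, noise_sd=0.0,
        peak_distances=[(2.0, 1.0, 1.5)], bleach_rate=5e-4, seed=2,
    )
    movie, gt = syn.make_growing_hair_movie(gt, 300, "fluorescence")
    return movie, gt


@pytest.fixture(scope="session")
def apical_fluor_track(apical_fluor):
    movie, gt = apical_fluor
    return trk.track_tip(movie)
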