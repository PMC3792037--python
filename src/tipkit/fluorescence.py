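"""Tip-fluorescence quantification.

Camera-noise removal by dark-frame subtraction, photobleaching correction
by log-linear regression against a first-order exponential decay,
coefficient of variation of the bleach-corrected apical signal, and the
PM/CS recruitment ratio (mean plasma-membrane line intensity over mean
cytosol intensity sampled a fixed distance behind the membrane).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .movie import Movie, bilinear_sample
from .tracking import TipROIs, TipTrack


@dataclass
class IntensitySeries:
    """A tip-intensity time course with its fitted bleach model.

    ``corrected[i] = raw[i] / (A * exp(-k * t[i]))`` — dividing by the
    fitted first-order decay makes the series dimensionless with mean ~1.
    """

    times_s: np.ndarray
    raw: np.ndarray
    corrected: np.ndarray
    bleach_amplitude: float      # A > 0
    bleach_rate: float           # k, 1/s

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.times_s, "raw": self.raw, "corrected": self.corrected}
        )


@dataclass
class PMCSSeries:
    """Per-frame plasma-membrane and cytosol intensities and their ratio."""

    times_s: np.ndarray
    pm: np.ndarray
    cs: np.ndarray
    ratio: np.ndarray
    mean_ratio: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.times_s, "pm": self.pm, "cs": self.cs, "ratio": self.ratio}
        )


def dark_subtract(movie: Movie, dark: np.ndarray) -> Movie:
    """Subtract a dark background frame from every frame, clamping at 0."""
    dark = np.asarray(dark, dtype=float)
    if dark.shape != movie.frames.shape[1:]:
        raise ValueError(
            f"dark frame shape {dark.shape} does not match movie frames "
            f"{movie.frames.shape[1:]}"
        )
    frames = np.clip(movie.frames - dark[None], 0.0, None)
    return Movie(frames, movie.pixel_size, movie.frame_interval, movie.channel_label)


def bleach_correct(times_s: np.ndarray, raw: np.ndarray) -> IntensitySeries:
    """Fit ``ln(raw) = ln A - k t`` by ordinary least squares and divide it out.

    All frames enter the regression, fluctuation peaks included.  Raw
    values must be strictly positive (run dark subtraction first and check
    the ROI does not leave the cell).
    """
    times_s = np.asarray(times_s, dtype=float)
    raw = np.asarray(raw, dtype=float)
    if raw.size < 3:
        raise ValueError("bleach correction needs at least 3 time points")
    if np.any(raw <= 0):
        raise ValueError(
            "non-positive intensities; check dark subtraction / ROI placement"
        )
    slope, intercept = np.polyfit(times_s, np.log(raw), 1)
    A = float(np.exp(intercept))
    k = float(-slope)
    corrected = raw / (A * np.exp(-k * times_s))
    return IntensitySeries(times_s, raw, corrected, A, k)


def coefficient_of_variation(values: np.ndarray) -> float:
    """Sample standard deviation (n-1) divided by the mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs at least 2 points")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero-mean series")
    return float(values.std(ddof=1) / mean)


def roi_mean_series(movie: Movie, track: TipTrack, roi: TipROIs) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity inside the moving circular ROI, per valid frame.

    Pixels enter the mean when their centre lies inside the circle and
    inside the segmented cell.
    """
    ps = movie.pixel_size
    times, means = [], []
    h, w = movie.frames.shape[1:]
    rows = (np.arange(h) + 0.5) * ps
    cols = (np.arange(w) + 0.5) * ps
    cgrid = np.meshgrid(rows, cols, indexing="ij")
    for t in np.nonzero(roi.valid)[0]:
        c = roi.circle_centers_um[t]
        inside = (cgrid[0] - c[0]) ** 2 + (cgrid[1] - c[1]) ** 2 <= roi.circle_radius_um**2
        sel = inside & track.masks[t]
        if not sel.any():
            continue
        times.append(t * movie.frame_interval)
        means.append(float(movie.frames[t][sel].mean()))
    return np.asarray(times), np.asarray(means)


def tip_cv(
    movie: Movie,
    track: TipTrack,
    roi: TipROIs | None = None,
    radius_um: float = 2.0,
) -> float:
    """Coefficient of variation of the bleach-corrected apical signal.

    The per-frame mean inside the tracked circular tip ROI is bleach
    corrected, then its CV is returned — one scalar per cell.
    """
    from .tracking import apical_roi

    if roi is None:
        roi = apical_roi(track, radius_um)
    times, raw = roi_mean_series(movie, track, roi)
    series = bleach_correct(times, raw)
    return coefficient_of_variation(series.corrected)


def pm_cs_ratio(movie: Movie, rois: TipROIs, min_valid_frames: int = 10) -> PMCSSeries:
    """PM/CS ratio per frame and its per-cell mean over the observation window.

    The membrane intensity is estimated per frame by a two-parameter
    linear fit of the radial profile to the cell's calibrated membrane
    edge model (cytosol plateau + membrane band + background, blur and
    boundary position frozen from :func:`tipkit.tracking.pm_cs_rois`);
    this removes the partial-volume attenuation a point sample of a
    ~0.4 µm membrane band suffers.  The cytosol intensity is the mean
    bilinear sample along the line ``cs_offset_um`` behind the membrane.
    """
    from .tracking import _membrane_profile_model

    meta = rois.meta
    ring_w = meta["ring_width_um"]
    b, sigma = meta["boundary_offset_um"], meta["blur_sigma_um"]
    R0 = meta["cap_radius_um"]
    ps = movie.pixel_size
    deltas = np.arange(-1.2, 1.2 + 0.01, 0.25 * ps)
    # basis of the frozen edge model: profile = cs*base_cs + pm*base_pm
    base_cs = _membrane_profile_model(deltas, 1.0, 0.0, b, sigma, ring_w)
    base_pm = _membrane_profile_model(deltas, 0.0, 1.0, b, sigma, ring_w)
    design = np.column_stack([base_cs, base_pm])

    vi = np.nonzero(rois.valid)[0]
    times, pm_vals, cs_vals = [], [], []
    for t in vi:
        centre = meta["centres_um"][t]
        rhat = meta["rhats"][t]
        pts = centre[None, None, :] + (R0 + deltas[:, None, None]) * rhat[None, :, :]
        prof = bilinear_sample(movie.frames[t], pts / ps - 0.5).mean(axis=1)
        coef, *_ = np.linalg.lstsq(design, prof, rcond=None)
        pm = float(coef[1])
        cs_pts = rois.cs_points_um[t] / ps - 0.5
        cs = float(bilinear_sample(movie.frames[t], cs_pts).mean())
        if cs <= 0:
            continue
        times.append(t * movie.frame_interval)
        pm_vals.append(pm)
        cs_vals.append(cs)
    if len(times) < min_valid_frames:
        raise ValueError(
            f"only {len(times)} valid frames for PM/CS (need {min_valid_frames})"
        )
    pm_arr = np.asarray(pm_vals)
    cs_arr = np.asarray(cs_vals)
    ratio = pm_arr / cs_arr
    return PMCSSeries(np.asarray(times), pm_arr, cs_arr, ratio, float(ratio.mean()))
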