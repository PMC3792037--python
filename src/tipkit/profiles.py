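"""Axial intensity distributions relative to the root-hair tip.

For every frame the hair is resampled into the axis frame (apex at
axial distance 0, distances increasing toward the base); the mean
intensity of each axial distance bin, averaged over the transverse extent
of the cell, gives a per-frame profile that is normalized to its maximum
(= 100%) and then averaged over frames.  Peak positions of these
time-averaged profiles locate markers relative to the apex.  Kymographs
and fixed-depth tip-window traces visualize the same geometry over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .movie import Movie, bilinear_sample
from .tracking import TipTrack


@dataclass
class AxialProfile:
    """Normalized mean intensity vs distance from the apex."""

    distances_um: np.ndarray        # bin centres, 0 at the tip
    per_frame: np.ndarray           # (n_valid_frames, n_bins), % of frame max
    mean_profile: np.ndarray        # time average, %
    n_frames: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "distance_um": self.distances_um,
                "mean_norm_intensity_pct": self.mean_profile,
                "n_frames": self.n_frames,
            }
        )


def axial_profile(
    movie: Movie,
    track: TipTrack,
    max_dist_um: float = 12.0,
    normalize_per_frame: bool = True,
) -> AxialProfile:
    """Per-frame axial profiles, normalized to max = 100%, then averaged.

    Each frame is resampled on a grid aligned with that frame's hair
    axis (bilinear interpolation); every axial bin averages the samples
    whose positions fall inside the segmented cell.  Frames with invalid
    tracking are skipped.  ``normalize_per_frame=False`` averages raw
    profiles first and normalizes the average instead (sensitivity check).
    """
    ps = movie.pixel_size
    nbins = int(round(max_dist_um / ps))
    dists = (np.arange(nbins) + 0.5) * ps
    half_w = None
    profiles = []
    for t in np.nonzero(track.valid)[0]:
        u_base = track.axis[t]
        normal = np.array([-u_base[1], u_base[0]])
        apex = track.apex_um[t]
        if half_w is None:
            from .tracking import hair_width_um

            # sample 80% of the half-width; the in-cell mask test trims the
            # rest (skip frames whose mask is too short to estimate a width)
            try:
                half_w = 0.4 * hair_width_um(track, t)
            except ValueError:
                continue
        tcoords = np.arange(-half_w, half_w + ps / 2, ps)
        # sample grid: rows = axial bins, cols = transverse offsets
        pts = (
            apex[None, None, :]
            + dists[:, None, None] * u_base[None, None, :]
            + tcoords[None, :, None] * normal[None, None, :]
        )
        vals = bilinear_sample(movie.frames[t], pts / ps - 0.5)
        idx = np.clip(np.round(pts / ps - 0.5).astype(int), 0, None)
        idx[..., 0] = np.clip(idx[..., 0], 0, movie.frames.shape[1] - 1)
        idx[..., 1] = np.clip(idx[..., 1], 0, movie.frames.shape[2] - 1)
        # erode the mask by 1 px so boundary samples (bilinear mixes with
        # the dark background) do not depress the bin means
        from scipy.ndimage import binary_erosion

        core = binary_erosion(track.masks[t], np.ones((3, 3)), border_value=1)
        in_cell = core[idx[..., 0], idx[..., 1]]
        with np.errstate(invalid="ignore"):
            prof = np.where(
                in_cell.any(axis=1),
                np.nansum(vals * in_cell, axis=1) / np.maximum(in_cell.sum(axis=1), 1),
                np.nan,
            )
        if normalize_per_frame:
            m = np.nanmax(prof)
            if not (m > 0):
                continue
            prof = prof / m * 100.0
        profiles.append(prof)
    if not profiles:
        raise ValueError("no valid frames for axial profile")
    per_frame = np.vstack(profiles)
    mean_prof = np.nanmean(per_frame, axis=0)
    if not normalize_per_frame:
        mean_prof = mean_prof / np.nanmax(mean_prof) * 100.0
    return AxialProfile(dists, per_frame, mean_prof, len(profiles))


def peak_distance(profile: AxialProfile) -> tuple[float, bool]:
    """Distance bin of the global maximum of the time-averaged profile.

    Returns (distance µm, tie_flag); ties across a plateau resolve to the
    centroid of the tied bins with the flag set.
    """
    prof = profile.mean_profile
    m = np.nanmax(prof)
    tied = np.nonzero(prof >= m - 1e-9)[0]
    if len(tied) == 1:
        return float(profile.distances_um[tied[0]]), False
    return float(profile.distances_um[tied].mean()), True


def ratio_landmarks(
    prof_a: AxialProfile,
    prof_b: AxialProfile,
    floor_pct: float = 5.0,
    extremum: str = "max",
) -> tuple[float | None, float | None]:
    """Landmarks of two co-registered normalized profiles.

    Returns ``(crossing_um, extremal_ratio_um)``: the first axial position
    where the two normalized profiles intersect (linear interpolation
    between bins), and the position where B/A is maximal (or minimal, per
    ``extremum``) among bins where A exceeds ``floor_pct``.  A missing
    crossing (identical or non-intersecting profiles) returns None.
    """
    if prof_a.distances_um.shape != prof_b.distances_um.shape or not np.allclose(
        prof_a.distances_um, prof_b.distances_um
    ):
        raise ValueError("profiles must share the same distance bins")
    a, b = prof_a.mean_profile, prof_b.mean_profile
    d = prof_a.distances_um
    diff = b - a
    crossing = None
    if np.allclose(diff, 0.0):
        return None, None
    sign = np.sign(diff)
    for i in range(len(d) - 1):
        if sign[i] == 0:
            crossing = float(d[i])
            break
        if sign[i] != sign[i + 1] and sign[i + 1] != 0:
            frac = diff[i] / (diff[i] - diff[i + 1])
            crossing = float(d[i] + frac * (d[i + 1] - d[i]))
            break
        if sign[i + 1] == 0:
            crossing = float(d[i + 1])
            break
    valid = a > floor_pct
    extremal = None
    if valid.any():
        ratio = np.where(valid, b / np.where(valid, a, 1.0), np.nan)
        idx = np.nanargmax(ratio) if extremum == "max" else np.nanargmin(ratio)
        extremal = float(d[idx])
    return crossing, extremal


def kymograph(movie: Movie, track: TipTrack) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Space-time image along the hair axis: one row per frame.

    The sampling line is fixed in the lab frame (axis of the last valid
    frame, anchored at its apex), so a growing tip traces a curve.
    Returns ``(kymo, axial_positions_um, tip_position_um_per_frame)``:
    axial positions increase tip-ward along the line and the per-frame tip
    positions are the apex projections onto it (NaN where invalid).
    """
    vi = np.nonzero(track.valid)[0]
    if len(vi) < 2:
        raise ValueError("kymograph needs at least 2 valid frames")
    last = vi[-1]
    u_tip = -track.axis[last]
    origin = track.apex_um[vi[0]] - 5.0 * u_tip  # start a little behind first apex
    ps = movie.pixel_size
    h, w = movie.frames.shape[1:]
    max_len = np.hypot(h * ps, w * ps)
    s = np.arange(0.0, max_len, ps)
    pts = origin[None, :] + s[:, None] * u_tip[None, :]
    inside = (
        (pts[:, 0] >= 0) & (pts[:, 0] <= h * ps) & (pts[:, 1] >= 0) & (pts[:, 1] <= w * ps)
    )
    s = s[inside]
    pts = pts[inside]
    rows = [bilinear_sample(movie.frames[t], pts / ps - 0.5) for t in range(movie.n_frames)]
    kymo = np.vstack(rows)
    tip_s = np.full(movie.n_frames, np.nan)
    for t in vi:
        tip_s[t] = float((track.apex_um[t] - origin) @ u_tip)
    return kymo, s, tip_s


def tip_window_intensity(
    movie: Movie,
    track: TipTrack,
    depth_um: float = 2.0,
) -> np.ndarray:
    """Mean intensity of the cell region within ``depth_um`` of the apex.

    One value per frame (NaN where tracking is invalid), following the
    moving tip.
    """
    if not depth_um > 0:
        raise ValueError("depth must be > 0 µm")
    ps = movie.pixel_size
    h, w = movie.frames.shape[1:]
    rows = (np.arange(h) + 0.5) * ps
    cols = (np.arange(w) + 0.5) * ps
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = np.full(movie.n_frames, np.nan)
    for t in np.nonzero(track.valid)[0]:
        u_base = track.axis[t]
        apex = track.apex_um[t]
        axial = (rr - apex[0]) * u_base[0] + (cc - apex[1]) * u_base[1]
        sel = track.masks[t] & (axial >= 0) & (axial <= depth_um)
        if sel.any():
            out[t] = float(movie.frames[t][sel].mean())
    return out
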