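"""Synthetic time-lapse movies with known ground truth.

Every image class the analysis pipeline consumes can be generated here
with all generative parameters recorded, so each estimator is testable by
parameter recovery without any microscope data:

* a tube-shaped cell (straight shank + hemispherical apical cap) that
  elongates at a constant or sinusoidally oscillating rate, rendered
  either with DIC-like signed edge contrast or as a fluorescence channel
  whose axial intensity profile is a sum of Gaussian components anchored
  at the moving apex;
* a plasma-membrane ring along the cell outline with a configurable
  ring/interior intensity ratio;
* spatially unstructured textures whose frame-to-frame Pearson
  correlation decays with a known constant (an AR(1) process mixed with a
  static field) — the analytic oracle for the cross-correlation decay
  statistic;
* still images of bright line segments for the filament detector.

First-order photobleaching, sinusoidal amplitude modulation of the tip
signal, and additive Gaussian (optionally Poisson) camera noise can be
imposed on any fluorescence movie.

Rasterization places pixel centers at (i+0.5, j+0.5) and anti-aliases by
2×2 supersampling, so geometric ground truth is sub-pixel accurate.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .movie import Movie

TWO_PI = 2.0 * math.pi


@dataclass
class GroundTruth:
    """Simulation parameters, stored exactly as used, plus per-frame echoes.

    Units: lengths µm, times s, rates µm/min, bleach_rate 1/s.
    ``peak_distances`` lists axial fluorescence components as
    ``(distance from apex µm, relative amplitude, Gaussian sigma µm)``.
    """

    # geometry / kinetics
    v0: float = 0.0                     # mean elongation rate, µm/min
    osc_amplitude: float = 0.0          # a in v0*(1 + a*sin(2*pi*t/tau))
    osc_period_s: float = 300.0
    tube_width_um: float = 8.0
    initial_length_um: float = 10.0
    axis_angle_deg: float = 0.0         # 0 = growing along +col
    entry_row_um: float | None = None   # default: vertical frame centre

    # fluorescence
    peak_distances: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(2.0, 1.0, 1.5)]
    )
    baseline: float = 0.2               # uniform in-cell floor, rel. to amplitude
    amplitude: float = 100.0            # intensity units of a rel-amp-1 component
    pm_cs_ratio: float = 1.0
    pm_ring_um: float = 0.4             # membrane ring thickness
    bleach_rate: float = 0.0            # 1/s, first-order decay
    mod_depth: float = 0.0              # tip amplitude modulation 1+m*sin
    mod_period_s: float = 60.0

    # AR(1) texture
    ar1_rho: float = 0.9
    static_fraction: float = 0.0        # lambda in [0, 1]

    # camera
    noise_sd: float = 0.0
    poisson: bool = False
    dic_mid: float = 100.0
    dic_edge_amp: float = 50.0

    # calibration
    pixel_size: float = 0.2             # µm/px (63x objective with 2x binning)
    frame_interval: float = 30.0        # s
    frame_shape: tuple[int, int] | None = None  # (H, W) px; None = auto-fit

    seed: int = 0

    # echoes written by the generators
    tip_positions_um: np.ndarray | None = None   # (T, 2) (row, col) µm
    times_s: np.ndarray | None = None
    segments_um: list | None = None
    segment_lengths_um: list | None = None

    def rate_um_per_min(self, t_s: np.ndarray | float) -> np.ndarray | float:
        """Instantaneous elongation rate v(t) in µm/min."""
        return self.v0 * (1.0 + self.osc_amplitude * np.sin(TWO_PI * np.asarray(t_s) / self.osc_period_s))

    def displacement_um(self, t_s: np.ndarray | float) -> np.ndarray | float:
        """Tip displacement since t=0 in µm (closed-form integral of v)."""
        t = np.asarray(t_s, dtype=float)
        osc = self.osc_amplitude * self.osc_period_s / TWO_PI * (1.0 - np.cos(TWO_PI * t / self.osc_period_s))
        return self.v0 / 60.0 * (t + osc)

    @property
    def axis_unit(self) -> np.ndarray:
        """Unit growth direction as (d_row, d_col)."""
        th = math.radians(self.axis_angle_deg)
        return np.array([math.sin(th), math.cos(th)])

    def save(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        Path(path).write_text(json.dumps(d, indent=1))


def _auto_frame_shape(gt: GroundTruth, duration_s: float) -> tuple[int, int]:
    final_len = gt.initial_length_um + float(gt.displacement_um(duration_s))
    u = gt.axis_unit
    margin = 2.0  # µm
    w_um = abs(u[1]) * (final_len + margin) + abs(u[0]) * gt.tube_width_um + margin
    h_um = abs(u[0]) * (final_len + margin) + gt.tube_width_um + 2 * margin
    return (int(math.ceil(h_um / gt.pixel_size)), int(math.ceil(w_um / gt.pixel_size)))


def _subpixel_grid(shape: tuple[int, int], pixel_size: float):
    """(row, col) µm coordinates of 2×2 supersample points, shape (2H, 2W)."""
    h, w = shape
    rr = (np.arange(2 * h) + 0.5) / 2.0 * pixel_size
    cc = (np.arange(2 * w) + 0.5) / 2.0 * pixel_size
    return np.meshgrid(rr, cc, indexing="ij")


def _downsample2(a: np.ndarray) -> np.ndarray:
    return a.reshape(a.shape[0] // 2, 2, a.shape[1] // 2, 2).mean(axis=(1, 3))


def _tube_fields(gt: GroundTruth, shape, tip_um, base_um):
    """Signed distance to the tube surface and axial distance from the apex,
    both on the 2× supersampled grid (µm)."""
    rr, cc = _subpixel_grid(shape, gt.pixel_size)
    u = gt.axis_unit
    # spine segment from a point behind the entry border to the cap centre
    a = base_um - 5.0 * gt.tube_width_um * u
    b = tip_um - 0.5 * gt.tube_width_um * u
    ab = b - a
    denom = float(ab @ ab)
    pr = rr - a[0]
    pc = cc - a[1]
    t = np.clip((pr * ab[0] + pc * ab[1]) / denom, 0.0, 1.0)
    dr = pr - t * ab[0]
    dc = pc - t * ab[1]
    dist = np.hypot(dr, dc)
    signed = 0.5 * gt.tube_width_um - dist     # > 0 inside the cell
    axial = (tip_um[0] - rr) * u[0] + (tip_um[1] - cc) * u[1]
    return signed, np.clip(axial, 0.0, None)


def _check_in_frame(gt: GroundTruth, shape, tips_um) -> None:
    h_um = shape[0] * gt.pixel_size
    w_um = shape[1] * gt.pixel_size
    half = 0.5 * gt.tube_width_um
    for i, tip in enumerate(tips_um):
        if not (half <= tip[0] <= h_um - half and 0.0 <= tip[1] <= w_um - gt.pixel_size):
            raise ValueError(f"tube leaves the field at frame {i} (tip at {tip} µm)")


def _apply_camera(frames: np.ndarray, gt: GroundTruth, rng) -> np.ndarray:
    if gt.poisson:
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
    if gt.noise_sd > 0:
        frames = frames + rng.normal(0.0, gt.noise_sd, frames.shape)
    return np.clip(frames, 0.0, None)


def _tip_series(gt: GroundTruth, shape, n_frames: int):
    times = np.arange(n_frames) * gt.frame_interval
    u = gt.axis_unit
    entry_row = gt.entry_row_um if gt.entry_row_um is not None else 0.5 * shape[0] * gt.pixel_size
    base = np.array([entry_row, 0.0])
    lengths = gt.initial_length_um + gt.displacement_um(times)
    tips = base[None, :] + lengths[:, None] * u[None, :]
    return times, base, tips


def make_growing_hair_movie(
    gt: GroundTruth, duration_s: float, mode: str = "dic_like"
) -> tuple[Movie, GroundTruth]:
    """Render an elongating root hair.

    ``dic_like`` draws signed edge relief (bright on one flank, dark on the
    other) on a mid-gray background; ``fluorescence`` fills the cell with
    the summed Gaussian axial components anchored at the moving apex,
    bleached by ``exp(-bleach_rate*t)`` and optionally amplitude-modulated.
    """
    if mode not in ("dic_like", "fluorescence"):
        raise ValueError(f"unknown mode {mode!r}")
    if duration_s < 2 * gt.frame_interval:
        raise ValueError("duration must cover at least 2 frame intervals")
    n_frames = int(round(duration_s / gt.frame_interval)) + 1
    shape = gt.frame_shape or _auto_frame_shape(gt, duration_s)
    times, base, tips = _tip_series(gt, shape, n_frames)
    _check_in_frame(gt, shape, tips)

    rng = np.random.default_rng(gt.seed)
    frames = np.empty((n_frames, *shape))
    grad_norm = None
    for i, t in enumerate(times):
        signed, axial = _tube_fields(gt, shape, tips[i], base)
        inside = signed > 0
        if mode == "dic_like":
            cov = _downsample2(inside.astype(float))
            g = gaussian_filter(cov, 1.0)
            gr, gc = np.gradient(g)
            phi = math.radians(gt.axis_angle_deg + 45.0)
            rel = math.sin(phi) * gr + math.cos(phi) * gc
            if grad_norm is None:
                grad_norm = np.abs(rel).max() or 1.0
            frames[i] = gt.dic_mid + gt.dic_edge_amp * rel / grad_norm
        else:
            prof = np.full(axial.shape, gt.baseline)
            for mu, amp, sigma in gt.peak_distances:
                prof = prof + amp * np.exp(-((axial - mu) ** 2) / (2.0 * sigma**2))
            mod = 1.0 + gt.mod_depth * math.sin(TWO_PI * t / gt.mod_period_s)
            img = gt.amplitude * mod * prof * inside
            frames[i] = _downsample2(img) * math.exp(-gt.bleach_rate * t)
    frames = _apply_camera(frames, gt, rng)

    gt = dataclasses.replace(gt, frame_shape=shape)
    gt.tip_positions_um = tips
    gt.times_s = times
    label = "DIC" if mode == "dic_like" else "fluorescence"
    return Movie(frames, gt.pixel_size, gt.frame_interval, label), gt


def make_pm_cs_movie(gt: GroundTruth, duration_s: float) -> tuple[Movie, GroundTruth]:
    """Tube movie with a thin membrane ring along the cell outline.

    The outermost ``pm_ring_um`` of the cell has mean intensity
    ``pm_cs_ratio`` × the interior (cytosol) intensity; the apex advances
    exactly as in :func:`make_growing_hair_movie`.
    """
    if not gt.pm_cs_ratio > 0:
        raise ValueError("pm_cs_ratio must be > 0")
    if gt.pm_ring_um < gt.pixel_size:
        raise ValueError(
            f"membrane ring ({gt.pm_ring_um} µm) thinner than 1 px at "
            f"{gt.pixel_size} µm/px"
        )
    n_frames = int(round(duration_s / gt.frame_interval)) + 1
    shape = gt.frame_shape or _auto_frame_shape(gt, duration_s)
    times, base, tips = _tip_series(gt, shape, n_frames)
    _check_in_frame(gt, shape, tips)

    rng = np.random.default_rng(gt.seed)
    cs = gt.amplitude
    frames = np.empty((n_frames, *shape))
    for i, t in enumerate(times):
        signed, _ = _tube_fields(gt, shape, tips[i], base)
        img = np.where(
            signed <= 0,
            0.0,
            np.where(signed < gt.pm_ring_um, gt.pm_cs_ratio * cs, cs),
        )
        frames[i] = _downsample2(img) * math.exp(-gt.bleach_rate * t)
    frames = _apply_camera(frames, gt, rng)

    gt = dataclasses.replace(gt, frame_shape=shape)
    gt.tip_positions_um = tips
    gt.times_s = times
    return Movie(frames, gt.pixel_size, gt.frame_interval, "PM-ring"), gt


def make_ar1_texture_movie(
    gt: GroundTruth, n_frames: int, tile_px: int = 64
) -> tuple[Movie, GroundTruth]:
    """Texture whose inter-frame correlation decays with a known constant.

    Per pixel, ``X_t = sqrt(lam)*S + sqrt(1-lam)*Z_t`` with S a fixed
    standard-normal field and Z an AR(1) chain of coefficient rho and unit
    marginal variance.  The expected Pearson correlation between frames
    Delta apart is ``lam + (1-lam)*rho**Delta`` — the single-exponential
    decay law with y0=1, plateau lam, K = -ln(rho) per frame.
    """
    rho, lam = gt.ar1_rho, gt.static_fraction
    if not 0.0 < rho <= 1.0:
        raise ValueError("ar1_rho must be in (0, 1]")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("static_fraction must be in [0, 1]")
    rng = np.random.default_rng(gt.seed)
    shape = (tile_px, tile_px)
    static = rng.standard_normal(shape)
    z = rng.standard_normal(shape)
    innov_sd = math.sqrt(1.0 - rho**2)
    frames = np.empty((n_frames, *shape))
    for t in range(n_frames):
        if t > 0:
            z = rho * z + innov_sd * rng.standard_normal(shape)
        frames[t] = 100.0 + 10.0 * (math.sqrt(lam) * static + math.sqrt(1.0 - lam) * z)
    frames = _apply_camera(frames, gt, rng)
    gt = dataclasses.replace(gt, frame_shape=shape)
    gt.times_s = np.arange(n_frames) * gt.frame_interval
    return Movie(frames, gt.pixel_size, gt.frame_interval, "AR1-texture"), gt


def make_filament_image(
    segments_um: list[tuple[tuple[float, float], tuple[float, float]]],
    width_px: float = 2.0,
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (100, 100),
    pixel_size: float = 0.2,
    amplitude: float = 100.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render anti-aliased bright line segments on a dark background.

    ``segments_um`` lists ((row0, col0), (row1, col1)) endpoints in µm.
    Ground truth records the true segment lengths and midpoints.
    """
    gt = GroundTruth(pixel_size=pixel_size, noise_sd=noise_sd, seed=seed, frame_shape=shape)
    rr, cc = _subpixel_grid(shape, pixel_size)
    half_w = 0.5 * width_px * pixel_size
    cov = np.zeros(rr.shape)
    lengths, mids = [], []
    for (r0, c0), (r1, c1) in segments_um:
        a = np.array([r0, c0])
        b = np.array([r1, c1])
        ab = b - a
        length = float(np.linalg.norm(ab)) or 1.0
        u = ab / length
        mid = 0.5 * (a + b)
        along = (rr - mid[0]) * u[0] + (cc - mid[1]) * u[1]
        across = -(rr - mid[0]) * u[1] + (cc - mid[1]) * u[0]
        # flat (butt) end caps: the rendered extent equals the true length
        inside = (np.abs(along) <= length / 2.0) & (np.abs(across) <= half_w)
        cov = np.maximum(cov, inside.astype(float))
        lengths.append(float(np.linalg.norm(ab)))
        mids.append(((r0 + r1) / 2.0, (c0 + c1) / 2.0))
    img = amplitude * _downsample2(cov)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, None)
    gt.segments_um = [list(map(list, s)) for s in segments_um]
    gt.segment_lengths_um = lengths
    return img, gt


# ---------------------------------------------------------------------------
# presets — the study conditions each analysis is validated under

def preset(name: str, seed: int = 0) -> GroundTruth:
    """Named parameter sets mirroring the imaging conditions of the study.

    ``wt``/``xik``: DIC growth movies at the genotype mean rates (1.26 and
    0.74 µm/min), 30 s frames.  ``osc``: oscillatory wild-type growth whose
    instantaneous peak rate v0*(1+a) is 2.33 µm/min.  ``raba4b``/``xik_marker``:
    fluorescence movies with a single Gaussian axial component at 2.0 or
    5.1 µm from the apex, 5 s frames, mild bleaching.  ``pmcs_wt``/``pmcs_xik``:
    membrane-ring movies at PM/CS ratios 1.01 and 0.93, 5 s frames.
    ``ar1``: the decay-statistic oracle at 1 s frames.  ``filaments`` returns
    a GroundTruth holding calibration for still filament images.
    """
    gts = {
        "wt": dict(v0=1.26, frame_interval=30.0, noise_sd=5.0),
        "xik": dict(v0=0.74, frame_interval=30.0, noise_sd=5.0),
        "osc": dict(v0=1.5, osc_amplitude=0.5533, osc_period_s=300.0,
                    frame_interval=30.0, noise_sd=5.0),
        "raba4b": dict(v0=1.0, frame_interval=5.0, bleach_rate=5e-4,
                       peak_distances=[(2.0, 1.0, 1.5)], noise_sd=20.0),
        "xik_marker": dict(v0=1.0, frame_interval=5.0, bleach_rate=5e-4,
                           peak_distances=[(5.1, 1.0, 1.5)], noise_sd=20.0),
        "pmcs_wt": dict(v0=0.3, frame_interval=5.0, pm_cs_ratio=1.01, noise_sd=10.0),
        "pmcs_xik": dict(v0=0.3, frame_interval=5.0, pm_cs_ratio=0.93, noise_sd=10.0),
        "ar1": dict(frame_interval=1.0, ar1_rho=0.9, static_fraction=0.0),
        "filaments": dict(),
    }
    if name not in gts:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(gts)}")
    return GroundTruth(seed=seed, **gts[name])
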