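"""Actin-dynamics statistic: decay of image cross-correlation over time.

The movie is tiled into 6×6 µm² squares (two interleaved grids displaced
by 3 µm).  For each tile, the zero-lag spatial Pearson correlation is
computed between *all* frame pairs and averaged per interval length; the
resulting decay curve is fitted with the single-phase exponential

    y = (y0 - p) * exp(-K * x) + p

whose decay constant K (1/s) quantifies how fast the imaged structure
rearranges and whose span (y0 - p) ranks tiles by usable signal.  The 10
largest-span tiles represent a cell; genotypes are compared by a rank-sum
test on per-cell mean K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .movie import Movie


@dataclass
class TileGrid:
    """Union of a base tile grid and one displaced by ``offset_um``."""

    size_um: float
    offset_um: float
    size_px: int
    origins_px: np.ndarray          # (n, 2) top-left (row, col) pixel indices
    pixel_size: float

    @property
    def n_tiles(self) -> int:
        return len(self.origins_px)

    def origins_um(self) -> np.ndarray:
        return self.origins_px * self.pixel_size


@dataclass
class XCorrCurve:
    """Mean inter-frame Pearson correlation vs interval for one tile."""

    intervals_s: np.ndarray
    y: np.ndarray
    n_pairs: np.ndarray
    frame_interval: float


@dataclass
class DecayFit:
    """Parameters of the single-phase exponential decay fit."""

    y0: float
    plateau: float
    K: float                        # 1/s, bounded >= 0
    span: float                     # y0 - plateau
    converged: bool
    rss: float
    origin_px: tuple[int, int] | None = None


@dataclass
class CellActivity:
    """Per-cell summary: all tile fits, the top-span selection, mean K."""

    fits: list[DecayFit]
    selected: list[DecayFit]
    mean_k: float


def tile_movie(movie: Movie, size_um: float = 6.0, offset_um: float = 3.0) -> TileGrid:
    """Two interleaved square grids covering the frame; border-clipped tiles
    are discarded, coincident tiles (offset 0) deduplicated."""
    ps = movie.pixel_size
    size_px = size_um / ps
    off_px = offset_um / ps
    if abs(size_px - round(size_px)) > 0.5 or abs(off_px - round(off_px)) > 0.5:
        raise ValueError("tile size and offset must be whole pixels within ±0.5 px")
    size_px = int(round(size_px))
    off_px = int(round(off_px))
    h, w = movie.frames.shape[1:]
    if size_px > h or size_px > w:
        raise ValueError(f"tile ({size_px} px) larger than frame {h}×{w}")
    origins = set()
    for r0, c0 in ((0, 0), (off_px, off_px)):
        for r in range(r0, h - size_px + 1, size_px):
            for c in range(c0, w - size_px + 1, size_px):
                origins.add((r, c))
    arr = np.array(sorted(origins), dtype=int)
    return TileGrid(size_um, offset_um, size_px, arr, ps)


def xcorr_curve(
    tile_stack: np.ndarray,
    frame_interval: float = 1.0,
    max_interval: int | None = None,
) -> XCorrCurve:
    """Mean Pearson correlation over all frame pairs at each interval.

    Implemented through the Gram matrix of the per-frame standardized
    pixel vectors, so all T(T-1)/2 pairs cost one matrix product.
    Zero-variance frames are excluded pairwise; an interval with no usable
    pair is dropped.
    """
    stack = np.asarray(tile_stack, dtype=float)
    T = stack.shape[0]
    if T < 3:
        raise ValueError("need at least 3 frames")
    flat = stack.reshape(T, -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat, axis=1)
    ok = norms > 0
    if not ok.any():
        raise ValueError("tile has zero intensity variance in every frame")
    flat[ok] /= norms[ok, None]
    gram = flat @ flat.T
    dmax = max_interval if max_interval is not None else max(T // 2, 1)
    dmax = min(dmax, T - 1)
    intervals, ys, counts = [], [], []
    for d in range(1, dmax + 1):
        pair_ok = ok[:-d] & ok[d:]
        if not pair_ok.any():
            continue
        vals = np.diagonal(gram, offset=d)[pair_ok]
        intervals.append(d * frame_interval)
        ys.append(float(vals.mean()))
        counts.append(int(pair_ok.sum()))
    return XCorrCurve(np.asarray(intervals), np.asarray(ys), np.asarray(counts), frame_interval)


def _decay(x, y0, p, k):
    return (y0 - p) * np.exp(-k * x) + p


def fit_decay(curve: XCorrCurve) -> DecayFit:
    """Nonlinear least squares of the single-phase exponential decay.

    Bounds: K >= 0, y0 and plateau in [-1, 1].  Initialization: y0 from
    the shortest interval, plateau from the last quartile of the curve,
    K from the interval where y first falls within 1/e of the plateau.
    Non-convergence is flagged, not raised — such tiles are excluded from
    the top-span selection downstream.
    """
    x, y = curve.intervals_s, curve.y
    if len(x) < 4:
        return DecayFit(np.nan, np.nan, np.nan, np.nan, False, np.nan)
    y0_init = float(y[0])
    p_init = float(y[-max(1, len(y) // 4):].mean())
    span_init = y0_init - p_init
    k_init = None
    if span_init > 0:
        below = np.nonzero(y <= p_init + span_init / np.e)[0]
        if below.size:
            xs = x[below[0]]
            k_init = 1.0 / xs if xs > 0 else None
    if k_init is None:
        k_init = 1.0 / float(np.median(x))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            popt, _ = optimize.curve_fit(
                _decay, x, y,
                p0=[np.clip(y0_init, -1, 1), np.clip(p_init, -1, 1), k_init],
                bounds=([-1.0, -1.0, 0.0], [1.0, 1.0, np.inf]),
                maxfev=5000,
                xtol=1e-13, ftol=1e-13, gtol=1e-13,
            )
    except (RuntimeError, ValueError):
        return DecayFit(np.nan, np.nan, np.nan, np.nan, False, np.nan)
    y0, p, k = map(float, popt)
    rss = float(((y - _decay(x, *popt)) ** 2).sum())
    return DecayFit(y0, p, k, y0 - p, True, rss)


def select_top_span(fits: list[DecayFit], n: int = 10) -> CellActivity:
    """The ``n`` converged fits with the largest span; ties broken by tile
    origin (row, then col) for determinism."""
    conv = [f for f in fits if f.converged]
    if not conv:
        raise ValueError("no converged decay fits in this cell")
    if len(conv) < n:
        warnings.warn(f"only {len(conv)} converged fits (requested {n})")
    key = lambda f: (-f.span, f.origin_px if f.origin_px is not None else (0, 0))
    selected = sorted(conv, key=key)[:n]
    mean_k = float(np.mean([f.K for f in selected]))
    return CellActivity(fits, selected, mean_k)


def analyze_cell(
    movie: Movie,
    size_um: float = 6.0,
    offset_um: float = 3.0,
    top_n: int = 10,
    max_interval: int | None = None,
) -> tuple[CellActivity, TileGrid]:
    """Tile → correlation curve → decay fit → top-span selection."""
    grid = tile_movie(movie, size_um, offset_um)
    fits = []
    for r, c in grid.origins_px:
        stack = movie.frames[:, r : r + grid.size_px, c : c + grid.size_px]
        try:
            curve = xcorr_curve(stack, movie.frame_interval, max_interval)
        except ValueError:
            fits.append(DecayFit(np.nan, np.nan, np.nan, np.nan, False, np.nan, (r, c)))
            continue
        fit = fit_decay(curve)
        fit.origin_px = (int(r), int(c))
        fits.append(fit)
    return select_top_span(fits, top_n), grid


def compare_activity(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test on per-cell mean decay constants.

    Exact null distribution for small tie-free samples, midrank/normal
    approximation otherwise (scipy's default policy).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 cells")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def activity_map(
    grid: TileGrid,
    activity: CellActivity,
    shape: tuple[int, int],
    k_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Render an RGB activity map: hue encodes the decay constant K,
    brightness the span; selected tiles are outlined in magenta.

    Tiles overlap (two interleaved grids), so each tile paints only its
    central half — the region it uniquely represents.
    """
    from matplotlib.colors import hsv_to_rgb

    conv = [f for f in activity.fits if f.converged]
    ks = np.array([f.K for f in conv]) if conv else np.array([0.0])
    if k_range is None:
        k_range = (float(ks.min()), float(ks.max()) or 1.0)
    kmin, kmax = k_range
    spans = np.array([max(f.span, 0.0) for f in conv]) if conv else np.array([1.0])
    smax = spans.max() or 1.0
    hsv = np.zeros((*shape, 3))
    q = grid.size_px // 4
    for f in activity.fits:
        if not f.converged or f.origin_px is None:
            continue
        r, c = f.origin_px
        sl = (slice(r + q, r + grid.size_px - q), slice(c + q, c + grid.size_px - q))
        knorm = 0.0 if kmax == kmin else (np.clip(f.K, kmin, kmax) - kmin) / (kmax - kmin)
        hsv[sl[0], sl[1], 0] = 0.66 * (1.0 - knorm)   # blue (slow) -> red (fast)
        hsv[sl[0], sl[1], 1] = 1.0
        hsv[sl[0], sl[1], 2] = max(f.span, 0.0) / smax
    rgb = hsv_to_rgb(hsv)
    selected_ids = {id(f) for f in activity.selected}
    for f in activity.fits:
        if id(f) in selected_ids and f.origin_px is not None:
            r, c = f.origin_px
            r1, c1 = r + grid.size_px - 1, c + grid.size_px - 1
            r1, c1 = min(r1, shape[0] - 1), min(c1, shape[1] - 1)
            rgb[r, c : c1 + 1] = rgb[r1, c : c1 + 1] = (1.0, 0.0, 1.0)
            rgb[r : r1 + 1, c] = rgb[r : r1 + 1, c1] = (1.0, 0.0, 1.0)
    return rgb
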