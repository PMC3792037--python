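"""Linear-feature (actin filament) detection and measurement.

Filaments are enhanced with a four-fold linear ("star-shaped") kernel:
at each pixel the mean intensity is probed along four centered line
orientations (0°, 45°, 90°, 135°); the response is the best orientation
minus the mean of the other three, so elongated structures stand out
while isotropic blobs cancel.  The response image is binarized with the
iterative intermeans (isodata) threshold, thinned to a one-pixel
skeleton, and traced into segments whose length must exceed a minimum
(1 µm in the original protocol).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

SQRT2 = float(np.sqrt(2.0))


@dataclass
class Segment:
    """One traced skeleton path (single-pixel wide, 8-connected)."""

    path_px: np.ndarray           # (n, 2) ordered (row, col) pixel indices
    length_um: float
    centroid_um: tuple[float, float]
    min_dist_to_tip_um: float | None = None


@dataclass
class FilamentSet:
    segments: list[Segment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def lengths_um(self) -> np.ndarray:
        return np.array([s.length_um for s in self.segments])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "segment_id": np.arange(len(self.segments)),
                "length_um": [s.length_um for s in self.segments],
                "centroid_row_um": [s.centroid_um[0] for s in self.segments],
                "centroid_col_um": [s.centroid_um[1] for s in self.segments],
                "min_dist_to_tip_um": [s.min_dist_to_tip_um for s in self.segments],
            }
        )


_PROBE_ANGLES = (0.0, 45.0, 90.0, 135.0)
_PROBE_NORMALS = {0.0: (1, 0), 45.0: (1, -1), 90.0: (0, 1), 135.0: (1, 1)}


def _line_kernel(length_px: int, angle_deg: float, supersample: int = 4) -> np.ndarray:
    """Anti-aliased 1-px-wide line probe of ``length_px`` through the kernel
    centre (rasterized by supersampling, normalized to unit mass)."""
    k = length_px + 2
    n = k * supersample
    coords = (np.arange(n) + 0.5) / supersample - k / 2.0
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    a = np.radians(angle_deg)
    u_r, u_c = np.sin(a), np.cos(a)
    along = yy * u_r + xx * u_c
    across = -yy * u_c + xx * u_r
    inside = (np.abs(along) <= length_px / 2.0) & (np.abs(across) <= 0.5)
    cov = inside.reshape(k, supersample, k, supersample).mean(axis=(1, 3))
    return cov / cov.sum()


def star_filter(
    image: np.ndarray,
    line_len_px: int = 7,
    smooth_sigma: float = 1.5,
    nms: bool = True,
) -> np.ndarray:
    """Four-orientation line-probe response, isotropic background suppressed.

    The image is Gaussian-smoothed first; for each pixel the mean
    intensity along four centered line probes (0°, 45°, 90°, 135°) is
    computed and the response is ``max(orientations) - mean(others)``,
    clipped at zero.  A uniform region or round blob gives (near) zero; a
    line scores high only along its own orientation.  With ``nms`` the
    response is additionally suppressed where it is not a local maximum
    across the winning orientation's normal, which thins each ridge to a
    single crest and removes the parallel ghost responses thick filaments
    produce.
    """
    if line_len_px % 2 == 0:
        warnings.warn("line_len_px must be odd; rounding up")
        line_len_px += 1
    img = ndimage.gaussian_filter(np.asarray(image, dtype=float), smooth_sigma)
    probes = np.stack(
        [ndimage.correlate(img, _line_kernel(line_len_px, a), mode="nearest")
         for a in _PROBE_ANGLES]
    )
    total = probes.sum(axis=0)
    best = probes.max(axis=0)
    winner = probes.argmax(axis=0)
    resp = np.clip(best - (total - best) / 3.0, 0.0, None)
    if not nms:
        return resp
    keep = np.zeros_like(resp, dtype=bool)
    padded = np.pad(resp, 2)
    h, w = resp.shape
    for i, a in enumerate(_PROBE_ANGLES):
        dr, dc = _PROBE_NORMALS[a]
        ok = winner == i
        # suppress against the normal neighbours at 1 and 2 px: the 2-px
        # check also removes the parallel side-lobe ghosts of the probes
        for d in (1, 2):
            n1 = padded[2 + d * dr : h + 2 + d * dr, 2 + d * dc : w + 2 + d * dc]
            n2 = padded[2 - d * dr : h + 2 - d * dr, 2 - d * dc : w + 2 - d * dc]
            ok = ok & (resp >= n1) & (resp >= n2)
        keep |= ok
    return resp * keep


def isodata_threshold(image: np.ndarray, tol: float = 0.5) -> tuple[float, np.ndarray]:
    """Iterative intermeans threshold and the resulting binary image.

    Starting from the global mean, the threshold is repeatedly replaced
    by the average of the means of the two classes it separates, until it
    moves less than ``tol`` intensity units.  Foreground is ``image > T``.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if lo == hi:
        raise ValueError("constant image has no isodata threshold")
    t = float(img.mean())
    for _ in range(500):
        low = img[img <= t]
        high = img[img > t]
        if low.size == 0 or high.size == 0:
            break
        t_new = 0.5 * (low.mean() + high.mean())
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new
    return float(t), img > t


def _prune_spurs(skel: np.ndarray, max_spur_px: int = 4, iterations: int = 3) -> np.ndarray:
    """Remove short side branches attached at skeleton junctions.

    Detection halos around filament ends produce few-pixel spurs; left in
    place, their junctions would chop the main ridge into fragments when
    paths are split at branch points.
    """
    skel = skel.copy()
    kernel = np.ones((3, 3))
    for _ in range(iterations):
        deg = ndimage.convolve(skel.astype(int), kernel, mode="constant") - 1
        endpoints = np.argwhere(skel & (deg == 1))
        removed_any = False
        for r, c in endpoints:
            if not skel[r, c]:
                continue
            trail = [(r, c)]
            prev = None
            cur = (r, c)
            hit_junction = False
            while len(trail) <= max_spur_px:
                nbs = [
                    (cur[0] + dr, cur[1] + dc)
                    for dr in (-1, 0, 1)
                    for dc in (-1, 0, 1)
                    if (dr or dc)
                    and 0 <= cur[0] + dr < skel.shape[0]
                    and 0 <= cur[1] + dc < skel.shape[1]
                    and skel[cur[0] + dr, cur[1] + dc]
                    and (cur[0] + dr, cur[1] + dc) != prev
                ]
                if len(nbs) != 1:
                    hit_junction = len(nbs) > 1
                    break
                prev = cur
                cur = nbs[0]
                if deg[cur] > 2:
                    hit_junction = True
                    break
                trail.append(cur)
            if hit_junction and len(trail) <= max_spur_px:
                for p in trail:
                    skel[p] = False
                removed_any = True
        if not removed_any:
            break
    return skel


def _trace_path(coords: set[tuple[int, int]]) -> np.ndarray:
    """Order the pixels of a degree-<=2 skeleton piece into a path."""
    neigh = {}
    for r, c in coords:
        nb = [
            (r + dr, c + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr or dc) and (r + dr, c + dc) in coords
        ]
        neigh[(r, c)] = nb
    ends = [p for p, nb in neigh.items() if len(nb) <= 1]
    start = min(ends) if ends else min(coords)  # cycles: arbitrary but stable
    path = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [p for p in neigh[cur] if p not in seen]
        if not nxt:
            break
        # prefer orthogonal continuation to avoid zig-zag double-counting
        nxt.sort(key=lambda p: (abs(p[0] - cur[0]) + abs(p[1] - cur[1]), p))
        cur = nxt[0]
        path.append(cur)
        seen.add(cur)
    return np.array(path)


def _path_length_um(path: np.ndarray, pixel_size: float) -> float:
    if len(path) < 2:
        return 0.0
    steps = np.abs(np.diff(path, axis=0))
    step_len = np.where(steps.sum(axis=1) == 2, SQRT2, 1.0)
    return float(step_len.sum() * pixel_size)


def _halfmax_length_px(path: np.ndarray, intensity: np.ndarray) -> float | None:
    """Sub-pixel length of a straight filament: distance between the
    half-maximum crossings of the intensity profile along the fitted line.

    Returns None when the path is not well described by a straight line
    (RMS transverse residual > 1 px), in which case the caller falls back
    to the chessboard-corrected path length.  This undoes both the end
    smear of the line-probe response and skeleton grid quantization.
    """
    from .movie import bilinear_sample

    if len(path) < 3:
        return None
    centred = path - path.mean(axis=0)
    cov = centred.T @ centred / len(path)
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, int(np.argmax(evals))]
    s = centred @ u
    perp = centred @ np.array([-u[1], u[0]])
    if float(np.sqrt(np.mean(perp**2))) > 1.0:
        return None
    step = 0.25
    grid = np.arange(s.min() - 4.0, s.max() + 4.0 + step, step)
    pts = path.mean(axis=0)[None, :] + grid[:, None] * u[None, :]
    prof = bilinear_sample(intensity, pts)
    core = prof[(grid >= s.min()) & (grid <= s.max())]
    if core.size == 0 or core.max() <= 0:
        return None
    # upper percentile, not median: short filaments' tapered ends would
    # otherwise drag the reference level down and inflate the length
    level = 0.5 * float(np.percentile(core, 80))
    above = np.nonzero(prof >= level)[0]
    if above.size < 2:
        return None
    i0, i1 = above[0], above[-1]
    lo = grid[i0]
    if i0 > 0 and prof[i0] != prof[i0 - 1]:
        lo -= step * (prof[i0] - level) / (prof[i0] - prof[i0 - 1])
    hi = grid[i1]
    if i1 + 1 < len(grid) and prof[i1] != prof[i1 + 1]:
        hi += step * (prof[i1] - level) / (prof[i1] - prof[i1 + 1])
    return float(hi - lo)


def _end_dir(path: np.ndarray, head: bool) -> np.ndarray:
    k = min(3, len(path) - 1)
    v = (path[0] - path[k]) if head else (path[-1] - path[-1 - k])
    n = np.linalg.norm(v)
    return v / n if n else np.array([0.0, 0.0])


def _stitch_pieces(paths: list[np.ndarray], gap_px: float = 2.9, min_cos: float = 0.8):
    """Merge skeleton pieces whose ends are close and collinear.

    The winning probe orientation alternates along lines oblique to all
    four probes, which can break one ridge into several pieces; branches
    that diverge at an angle (spur artifacts) are deliberately not merged.
    """
    paths = [p for p in paths if len(p)]
    merged = True
    while merged and len(paths) > 1:
        merged = False
        for i in range(len(paths)):
            for j in range(i + 1, len(paths)):
                a, b = paths[i], paths[j]
                best = None
                for a_end, b_end in ((True, True), (True, False), (False, True), (False, False)):
                    ea = a[0] if a_end else a[-1]
                    eb = b[0] if b_end else b[-1]
                    gap = eb - ea
                    dist = float(np.linalg.norm(gap))
                    if dist > gap_px or dist == 0:
                        continue
                    u = gap / dist
                    da = _end_dir(a, a_end)        # points outward from a
                    db = _end_dir(b, b_end)
                    if float(da @ u) < min_cos or float(db @ -u) < min_cos:
                        continue
                    best = (a_end, b_end)
                    break
                if best is None:
                    continue
                a_end, b_end = best
                left = a[::-1] if a_end else a
                right = b if b_end else b[::-1]
                paths[i] = np.vstack([left, right])
                paths.pop(j)
                merged = True
                break
            if merged:
                break
    return paths


def skeletonize_and_measure(
    binary: np.ndarray,
    min_len_um: float = 1.0,
    pixel_size: float = 0.2,
    tip_um: np.ndarray | None = None,
    intensity: np.ndarray | None = None,
) -> FilamentSet:
    """Thin to a 1-px skeleton, trace paths, measure, filter short pieces.

    Path length sums the inter-pixel step lengths (1 px orthogonal,
    sqrt(2) px diagonal) times the pixel size.  Branch points split the
    skeleton: each branch is its own segment.  An empty binary image
    yields an empty set.  ``tip_um`` (row, col µm) adds the minimum
    distance of any segment pixel to the tip.  When ``intensity`` (the
    smoothed source image) is given, path ends are trimmed to the
    half-median intensity level, undoing the end smear of the detection
    filter.
    """
    binary = np.asarray(binary).astype(bool)
    if not binary.any():
        return FilamentSet()
    skel = _prune_spurs(skeletonize(binary))
    # branch points have more than two 8-neighbours
    nb_count = ndimage.convolve(skel.astype(int), np.ones((3, 3)), mode="constant") - 1
    branch = skel & (nb_count > 2)
    pieces = skel & ~branch
    labels, n = ndimage.label(pieces, structure=np.ones((3, 3)))
    paths = []
    for i in range(1, n + 1):
        coords = set(map(tuple, np.argwhere(labels == i)))
        paths.append(_trace_path(coords))
    paths = _stitch_pieces(paths)
    segments = []
    for path in paths:
        if len(path) == 0:
            continue
        length = _path_length_um(path, pixel_size)
        # the raw skeleton length gates the minimum-length filter (short
        # spurs must not be rescued by the sub-pixel refinement, whose
        # profile can run into a neighbouring filament)
        if length < min_len_um:
            continue
        if intensity is not None:
            refined = _halfmax_length_px(path, intensity)
            if refined is not None:
                length = refined * pixel_size
        if length < min_len_um:
            continue
        centre = (path.mean(axis=0) + 0.5) * pixel_size
        dist = None
        if tip_um is not None:
            pts = (path + 0.5) * pixel_size
            dist = float(np.linalg.norm(pts - np.asarray(tip_um)[None], axis=1).min())
        segments.append(Segment(path, length, (float(centre[0]), float(centre[1])), dist))
    segments.sort(key=lambda s: -s.length_um)
    return FilamentSet(segments)


def detect_filaments(
    image: np.ndarray,
    pixel_size: float = 0.2,
    min_len_um: float = 1.0,
    line_len_px: int = 7,
    smooth_sigma: float = 1.5,
    tip_um: np.ndarray | None = None,
) -> FilamentSet:
    """Full detection pipeline: star filter → isodata → skeletonize → measure."""
    response = star_filter(image, line_len_px, smooth_sigma)
    positive = response[response > 0]
    if positive.size < 2 or positive.min() == positive.max():
        return FilamentSet()
    # threshold the response over its support: NMS zeroes most of the
    # background, and counting those structural zeros would drag the
    # intermeans threshold into the noise floor
    try:
        thr, _ = isodata_threshold(positive)
    except ValueError:
        return FilamentSet()
    binary = response > thr
    smoothed = ndimage.gaussian_filter(np.asarray(image, dtype=float), smooth_sigma)
    return skeletonize_and_measure(binary, min_len_um, pixel_size, tip_um, smoothed)


def frontmost_filament_distance(
    filament_sets: list[FilamentSet],
    apex_um: np.ndarray,
    pixel_size: float = 0.2,
) -> np.ndarray:
    """Per-frame distance of the closest filament pixel to the apex (µm).

    ``apex_um`` has shape (T, 2); frames without filaments (or without a
    valid apex) report NaN.
    """
    out = np.full(len(filament_sets), np.nan)
    for t, fs in enumerate(filament_sets):
        apex = np.asarray(apex_um[t], dtype=float)
        if not len(fs) or not np.all(np.isfinite(apex)):
            continue
        best = min(
            float(np.linalg.norm((s.path_px + 0.5) * pixel_size - apex[None], axis=1).min())
            for s in fs.segments
        )
        out[t] = best
    return out
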