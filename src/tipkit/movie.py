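"""Calibrated time-lapse movie container and TIFF I/O.

A :class:`Movie` is a T×H×W intensity stack together with the two
calibration constants every downstream measurement needs: the pixel size
in µm/pixel and the frame interval in seconds.  Physical positions are
always ``(row, col) index × pixel_size`` and are reported in µm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class Movie:
    """A calibrated T×H×W intensity stack.

    Parameters
    ----------
    frames
        Array of shape (T, H, W); intensities are arbitrary units >= 0.
    pixel_size
        µm per pixel (isotropic).
    frame_interval
        Seconds between consecutive frames.
    channel_label
        Free-text label of the imaged channel (e.g. ``"YFP-RabA4b"``).
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T×H×W stack with T >= 1")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("all intensities must be finite")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval

    def save(self, path: str | Path) -> None:
        """Write a multi-page TIFF plus a ``.json`` calibration sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.frames.astype(np.float32), photometric="minisblack")
        meta = {
            "pixel_size_um": self.pixel_size,
            "frame_interval_s": self.frame_interval,
            "channel_label": self.channel_label,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(
        cls,
        path: str | Path,
        pixel_size: float | None = None,
        frame_interval: float | None = None,
        channel_label: str = "",
    ) -> "Movie":
        """Read a multi-page TIFF.

        Calibration is taken from the ``.json`` sidecar when present;
        explicit arguments override it.
        """
        path = Path(path)
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            pixel_size = pixel_size or meta.get("pixel_size_um")
            frame_interval = frame_interval or meta.get("frame_interval_s")
            channel_label = channel_label or meta.get("channel_label", "")
        if pixel_size is None or frame_interval is None:
            raise ValueError(
                "pixel_size and frame_interval must be supplied "
                "(no calibration sidecar found)"
            )
        return cls(frames, pixel_size, frame_interval, channel_label)


def bilinear_sample(image: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Bilinearly interpolate ``image`` at real-valued (row, col) pixel coords.

    ``points`` has shape (..., 2).  Points outside the frame are clamped to
    the border (constant extrapolation), which keeps edge ROIs finite.
    """
    from scipy.ndimage import map_coordinates

    pts = np.asarray(points, dtype=float)
    flat = pts.reshape(-1, 2)
    vals = map_coordinates(image, [flat[:, 0], flat[:, 1]], order=1, mode="nearest")
    return vals.reshape(pts.shape[:-1])
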