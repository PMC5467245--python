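"""Movie container and TIFF round-trip with sidecar JSON metadata."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Movie", "write_movie", "read_movie"]


@dataclass
class Movie:
    """A calibrated time-lapse image stack.

    Attributes
    ----------
    pixels:
        Array of shape ``(n_frames, n_rows, n_cols)``; arbitrary intensity
        units (camera counts or photons).
    pixel_size_um:
        Lateral pixel size in micrometres (64 nm by default, typical for an
        EMCCD behind a 100x TIRF objective with extra magnification).
    frame_interval_s:
        Time between consecutive frames in seconds.
    """

    pixels: np.ndarray
    pixel_size_um: float = 0.064
    frame_interval_s: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[0] < 1:
            raise ValueError("pixels must be a (n_frames, rows, cols) stack with >=1 frame")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_movie(path: str | Path, movie: Movie) -> Path:
    """Write a multi-frame TIFF plus a sidecar JSON with calibration."""
    path = Path(path)
    tifffile.imwrite(path, movie.pixels)
    meta = {
        "pixel_size_um": movie.pixel_size_um,
        "frame_interval_s": movie.frame_interval_s,
        **movie.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, default=str))
    return path


def read_movie(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> Movie:
    """Read a multi-frame TIFF; calibration from the sidecar JSON unless overridden."""
    path = Path(path)
    pixels = tifffile.imread(path)
    if pixels.ndim == 2:
        pixels = pixels[None]
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um", 0.064)
    dt = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s", 1.0)
    return Movie(pixels=pixels, pixel_size_um=px, frame_interval_s=dt, metadata=meta)
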