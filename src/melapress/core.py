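"""Shared containers and image I/O for the pipeline.

Coordinate convention used everywhere: 0-based pixel indices, ``x`` is the
column index increasing rightward, ``y`` is the row index increasing
downward. Times are minutes for creep sequences and hours for colony
series; pixel size, when known, is micrometres per pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = [
    "ImageSequence",
    "load_frame",
    "load_sequence",
    "save_sequence",
    "to_uint8",
]


@dataclass
class ImageSequence:
    """Ordered stack of grayscale frames with acquisition times.

    Parameters
    ----------
    frames : ndarray, shape (n, rows, cols)
        Grayscale frames as floats (any range; matching and thresholding
        are intensity-scale invariant).
    times : ndarray, shape (n,)
        Acquisition time of each frame. Units are carried by the caller
        (minutes for creep imaging, hours for colony imaging).
    pixel_size_um : float, optional
        Physical pixel pitch in micrometres per pixel.
    """

    frames: np.ndarray
    times: np.ndarray
    pixel_size_um: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) stack")
        if len(self.times) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Rescale a float image to the full 8-bit range (CCD-export style)."""
    img = np.asarray(img, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round(255.0 * (img - lo) / (hi - lo)).astype(np.uint8)


def load_frame(path: str | Path) -> np.ndarray:
    """Read a single grayscale frame from TIFF/PNG; RGB is averaged."""
    arr = iio.imread(Path(path))
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:  # collapse colour channels
        arr = arr.mean(axis=-1)
    return arr


def load_sequence(path: str | Path, times=None, pixel_size_um=None) -> ImageSequence:
    """Read a multi-page TIFF (or single image) as an :class:`ImageSequence`.

    If a JSON sidecar ``<stem>.json`` exists it supplies ``times`` and
    ``pixel_size_um`` unless overridden.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        frames = tifffile.imread(path)
    else:
        frames = iio.imread(path)
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:  # pages with colour channels
        frames = frames.mean(axis=-1)

    sidecar = path.with_suffix(".json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if times is None:
        times = meta.get("times", np.arange(len(frames), dtype=float))
    if pixel_size_um is None:
        pixel_size_um = meta.get("pixel_size_um")
    return ImageSequence(frames, np.asarray(times, float), pixel_size_um, meta)


def save_sequence(seq: ImageSequence, path: str | Path, sidecar: dict | None = None) -> Path:
    """Write one page per frame as 8-bit TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    pages = np.stack([to_uint8(f) for f in seq.frames])
    tifffile.imwrite(path, pages)
    meta = {"times": seq.times.tolist(), "pixel_size_um": seq.pixel_size_um}
    meta.update(seq.meta)
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, default=float))
    return path
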