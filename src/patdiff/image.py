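"""2-D initial-pressure images and their on-disk representation.

A :class:`PressureImage` holds a single-channel map of acoustic pressure
(initial pressure for phantoms, signed amplitude for raw reconstructions,
[0, 255] after dataset normalization) together with its pixel spacing in mm.
Images are written as 32-bit single-channel TIFF with a JSON sidecar carrying
the physical metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import DataError

DYNAMIC_RANGE = 255.0
"""Intensity scale of normalized dataset images.

The diffusion noise level lambda=50 is defined relative to this scale: on a
[0, 1] range a stationary noise standard deviation of 50 would swamp the
signal, so all dataset images are min-max normalized to [0, 255].
"""


@dataclass
class PressureImage:
    """A 2-D pressure map on a regular grid centred on the ring centre."""

    pixels: np.ndarray
    spacing_mm: float = 0.1
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise DataError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if min(self.pixels.shape) < 8:
            raise DataError(f"image too small: {self.pixels.shape}, need >= 8x8")
        if not np.all(np.isfinite(self.pixels)):
            raise DataError("pixels contain non-finite values")
        if self.spacing_mm <= 0:
            raise DataError("spacing_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Physical (height, width) of the grid in mm."""
        h, w = self.pixels.shape
        return h * self.spacing_mm, w * self.spacing_mm

    def pixel_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of pixel centres in mm.

        Row index increases with y, column index with x; the grid centre sits
        at ``origin_mm``.
        """
        h, w = self.pixels.shape
        ys = (np.arange(h) - (h - 1) / 2.0) * self.spacing_mm + self.origin_mm[1]
        xs = (np.arange(w) - (w - 1) / 2.0) * self.spacing_mm + self.origin_mm[0]
        X, Y = np.meshgrid(xs, ys)
        return X, Y

    def max_radius_mm(self) -> float:
        """Largest distance of any pixel centre from the grid origin."""
        X, Y = self.pixel_coordinates()
        return float(np.hypot(X - self.origin_mm[0], Y - self.origin_mm[1]).max())

    def normalized(self, lo: float | None = None, hi: float | None = None) -> "PressureImage":
        """Min-max normalize onto [0, 255], optionally with external bounds."""
        lo = float(self.pixels.min()) if lo is None else lo
        hi = float(self.pixels.max()) if hi is None else hi
        if hi <= lo:
            out = np.zeros_like(self.pixels)
        else:
            out = np.clip((self.pixels - lo) / (hi - lo) * DYNAMIC_RANGE, 0.0, DYNAMIC_RANGE)
        return PressureImage(out, self.spacing_mm, self.origin_mm)


def save_image(img: PressureImage, path: str | Path, meta: dict | None = None) -> None:
    """Write a 32-bit TIFF plus a ``.json`` sidecar with spacing and metadata."""
    path = Path(path)
    tifffile.imwrite(path, img.pixels.astype(np.float32))
    sidecar = {"spacing_mm": img.spacing_mm, "origin_mm": list(img.origin_mm)}
    if meta:
        sidecar.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_image(path: str | Path) -> PressureImage:
    path = Path(path)
    pixels = np.asarray(tifffile.imread(path), dtype=np.float64)
    spacing, origin = 0.1, (0.0, 0.0)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        spacing = float(meta.get("spacing_mm", spacing))
        origin = tuple(meta.get("origin_mm", origin))  # type: ignore[assignment]
    return PressureImage(pixels, spacing, origin)
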