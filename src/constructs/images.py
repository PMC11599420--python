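"""Core raster containers: float images with a declared dynamic range, and
integer label masks.

Convention throughout the package: arrays are row-major with origin at the
top-left; shapes are stated H x W (x C).  Loss code works on images scaled
to [0, L] with L = 1 canonical; the generator's native range is [-1, 1] and
is rescaled at the loss boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Image:
    """H x W x C float pixel grid with values in [0, dynamic_range]."""

    pixels: np.ndarray
    dynamic_range: float = 1.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise ValueError(f"Image expects H x W x C pixels, got shape {self.pixels.shape}")
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be positive")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-6 or hi > self.dynamic_range + 1e-6:
            raise ValueError(
                f"pixel values [{lo:.4g}, {hi:.4g}] outside [0, {self.dynamic_range}]"
            )

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class LabelMask:
    """H x W integer class-ID grid; IDs lie in [0, num_classes)."""

    labels: np.ndarray
    num_classes: int
    class_names: list | None = field(default=None)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"LabelMask expects an H x W grid, got shape {self.labels.shape}")
        if self.labels.dtype.kind not in "iu":
            if not np.all(self.labels == np.round(self.labels)):
                raise ValueError("mask values must be integers")
            self.labels = self.labels.astype(np.int64)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.num_classes):
            raise ValueError(
                f"class IDs span [{self.labels.min()}, {self.labels.max()}] but "
                f"num_classes={self.num_classes}"
            )

    @property
    def shape(self):
        return self.labels.shape


def as_pixels(img, dynamic_range: float = 1.0) -> np.ndarray:
    """Accept an :class:`Image` or a bare array; return validated H x W x C pixels."""
    if isinstance(img, Image):
        return img.pixels
    return Image(np.asarray(img, dtype=np.float64), dynamic_range).pixels


def to_model_range(pixels01: np.ndarray) -> np.ndarray:
    """[0, 1] -> [-1, 1] (the generator's native range)."""
    return pixels01 * 2.0 - 1.0


def from_model_range(pixels_pm1: np.ndarray) -> np.ndarray:
    """[-1, 1] -> [0, 1], clipped against numerical spill."""
    return np.clip((pixels_pm1 + 1.0) * 0.5, 0.0, 1.0)
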