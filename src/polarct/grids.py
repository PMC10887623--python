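"""Core image containers shared across the package.

Two rasters appear throughout: the Cartesian attenuation image (``ImageGrid``)
and its polar-coordinate resampling (``PolarImage``).  Both are thin,
validated wrappers around float32 numpy arrays so that geometry metadata
(pixel size, polar center, maximum radius) travels with the pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ImageGrid", "PolarImage"]


@dataclass
class ImageGrid:
    """A 2D attenuation raster on a square Cartesian grid.

    Parameters
    ----------
    pixels
        ``(H, W)`` float array of attenuation values (arbitrary units).
    pixel_size
        Physical length per pixel (same unit in both axes).
    value_range
        Nominal display window ``(lo, hi)``; used for normalization windows
        and metric dynamic ranges, not enforced on the data.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("ImageGrid expects a 2D raster")
        h, w = self.pixels.shape
        if h < 16 or w < 16:
            raise ValueError(f"image too small: {h}x{w} (minimum 16x16)")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        lo, hi = self.value_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("value_range must be finite and ordered")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def is_square(self) -> bool:
        return self.pixels.shape[0] == self.pixels.shape[1]

    @property
    def size(self) -> int:
        """Side length in pixels (square images only)."""
        if not self.is_square:
            raise ValueError("size is defined for square images only")
        return self.pixels.shape[0]

    @property
    def physical_extent(self) -> float:
        """Physical side length of the grid."""
        return self.pixels.shape[0] * self.pixel_size

    def center(self) -> tuple[float, float]:
        """Image center ``(cx, cy)`` in pixel coordinates (col, row)."""
        h, w = self.pixels.shape
        return ((w - 1) / 2.0, (h - 1) / 2.0)

    def copy_with(self, pixels: np.ndarray) -> "ImageGrid":
        return ImageGrid(pixels, self.pixel_size, self.value_range)

    # -- persistence (lossless .npy + JSON sidecar) --------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.pixels.astype(np.float32))
        meta = {"pixel_size": self.pixel_size, "value_range": list(self.value_range)}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "ImageGrid":
        path = Path(path)
        pixels = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(pixels, meta["pixel_size"], tuple(meta["value_range"]))


@dataclass
class PolarImage:
    """An image resampled to polar coordinates about its center.

    Rows index the angle phi (uniform on ``[0, 2*pi)``); columns index the
    radius rho (column 0 is the center, the last column is ``r_max``).  With
    this layout a radially symmetric cupping field becomes constant along
    rows, i.e. a "horizontal" structure.
    """

    values: np.ndarray
    center: tuple[float, float]
    r_max: float
    rho_spacing: float = field(default=0.0)
    phi_spacing: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("PolarImage expects a 2D raster")
        n_phi, n_rho = self.values.shape
        if n_phi < 4 or n_rho < 4:
            raise ValueError("polar grid too small (minimum 4x4)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("polar image contains non-finite values")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.rho_spacing == 0.0:
            self.rho_spacing = self.r_max / (n_rho - 1)
        if self.phi_spacing == 0.0:
            self.phi_spacing = 2.0 * np.pi / n_phi

    @property
    def n_phi(self) -> int:
        return self.values.shape[0]

    @property
    def n_rho(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray) -> "PolarImage":
        return PolarImage(values, self.center, self.r_max, self.rho_spacing, self.phi_spacing)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.values.astype(np.float32))
        meta = {
            "center": list(self.center),
            "r_max": self.r_max,
            "rho_spacing": self.rho_spacing,
            "phi_spacing": self.phi_spacing,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "PolarImage":
        path = Path(path)
        values = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(values, tuple(meta["center"]), meta["r_max"], meta["rho_spacing"], meta["phi_spacing"])
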