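"""Polar-coordinate resampling of square Cartesian images.

Cup-shaped truncation artifacts are radially structured: a bright rim at
the FOV edge decaying toward the center.  Resampling the image onto a
(rho, phi) grid about its center turns those circular structures into
straight horizontal bands, which local filters (and convolutional
networks) separate far more easily.  The inverse transform returns the
processed image to Cartesian space; pixels outside the inscribed circle
carry no signal in FOV-limited CT images and are filled with zero.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .grids import ImageGrid, PolarImage

__all__ = ["to_polar", "from_polar"]


def to_polar(image: ImageGrid, n_rho: int | None = None, n_phi: int = 360) -> PolarImage:
    """Resample a square image to polar coordinates about its center.

    Rows are angles uniform on ``[0, 2*pi)``; columns are radii from 0 to
    the inscribed-circle radius (corners are discarded).  Bilinear sampling
    at ``(cx + rho*cos(phi), cy + rho*sin(phi))``.
    """
    if not image.is_square:
        raise ValueError("polar transform expects a square image")
    size = image.size
    if n_rho is None:
        n_rho = size // 2
    if n_rho < 4 or n_phi < 4:
        raise ValueError("polar grid too small")
    cx, cy = image.center()
    r_max = (size - 1) / 2.0
    rho = np.linspace(0.0, r_max, n_rho)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    cols = cx + rho[None, :] * np.cos(phi)[:, None]
    rows = cy + rho[None, :] * np.sin(phi)[:, None]
    vals = map_coordinates(image.pixels.astype(np.float64), [rows, cols], order=1, mode="nearest", prefilter=False)
    return PolarImage(vals.astype(np.float32), (cx, cy), r_max,
                      rho_spacing=r_max / (n_rho - 1), phi_spacing=2.0 * np.pi / n_phi)


def from_polar(polar: PolarImage, out_size: int) -> ImageGrid:
    """Invert the polar resampling onto a square Cartesian grid.

    Bilinear interpolation in (rho, phi) with wrap-around in phi (no seam
    at 0/2*pi); pixels beyond ``r_max`` are set to zero.
    """
    if out_size < 16:
        raise ValueError("out_size must be at least 16")
    n_phi, n_rho = polar.values.shape
    half = (out_size - 1) / 2.0
    yy, xx = np.mgrid[0:out_size, 0:out_size].astype(np.float64)
    x = xx - half
    y = yy - half
    # map Cartesian pixel offsets onto the polar image's radial scale
    scale = polar.r_max / ((out_size - 1) / 2.0)
    rho = np.hypot(x, y) * scale
    phi = np.mod(np.arctan2(y, x), 2.0 * np.pi)
    rho_idx = rho / polar.rho_spacing
    phi_idx = phi / polar.phi_spacing
    # pad one wrapped row so interpolation across the 2*pi seam is exact
    padded = np.vstack([polar.values, polar.values[:1]]).astype(np.float64)
    vals = map_coordinates(padded, [phi_idx, rho_idx], order=1, mode="nearest", prefilter=False)
    vals[rho > polar.r_max] = 0.0
    return ImageGrid(vals.astype(np.float32), pixel_size=1.0, value_range=(float(vals.min()), max(float(vals.max()), float(vals.min()) + 1e-6)))
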