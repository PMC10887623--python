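"""Fan-beam projection, sinogram truncation, and filtered backprojection.

This module manufactures the truncation (cupping) artifact: a phantom is
forward-projected with a fan-beam geometry (default 720 views over 2*pi),
the lateral channels of the sinogram are deleted, and the remainder is
reconstructed with ramp-filtered fan-beam FBP.  Reconstructing from the
laterally truncated data produces the characteristic radially increasing
bias with a bright rim at the edge of the retained field of view.

Geometry conventions
--------------------
All detector arithmetic happens on the *virtual detector*: the line through
the isocenter perpendicular to the central ray, with equidistant channel
positions ``s``.  For view angle ``beta`` the source sits at
``-SID * e(beta)`` with ``e = (cos beta, sin beta)``; a channel at offset
``s`` lies at ``s * e_perp``.  Physical coordinates are
``x = (col - cx) * pixel_size``, ``y = (row - cy) * pixel_size``.

The reconstruction follows the standard equidistant fan-beam FBP: cosine
pre-weighting ``SID / sqrt(SID^2 + s^2)``, convolution with the band-limited
ramp (Ram-Lak) kernel, and distance-weighted backprojection with the
``SID^2 / (SID + u)^2`` factor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from numba import njit
from scipy.ndimage import map_coordinates

from .grids import ImageGrid

__all__ = [
    "FanGeometry",
    "Sinogram",
    "forward_project",
    "truncate_sinogram",
    "fbp_reconstruct",
    "simulate_truncated_pair",
    "resample_to_recon_grid",
]


@dataclass
class FanGeometry:
    """Fan-beam acquisition description (equidistant detector).

    ``det_pitch`` is the physical channel width at the detector; internally
    channels are rescaled to the virtual detector at the isocenter.
    """

    n_views: int = 720
    source_iso: float = 400.0
    iso_det: float = 400.0
    n_det: int = 192
    det_pitch: float = 1.0
    angle_start: float = 0.0

    def __post_init__(self) -> None:
        if self.n_views < 4:
            raise ValueError("need at least 4 projection views")
        if self.source_iso <= 0 or self.iso_det <= 0:
            raise ValueError("distances must be positive")
        if self.n_det < 8:
            raise ValueError("need at least 8 detector channels")
        if self.det_pitch <= 0:
            raise ValueError("det_pitch must be positive")

    # -- derived quantities -------------------------------------------
    @property
    def magnification(self) -> float:
        return (self.source_iso + self.iso_det) / self.source_iso

    @property
    def pitch_iso(self) -> float:
        """Channel pitch rescaled to the virtual detector at the isocenter."""
        return self.det_pitch / self.magnification

    def channel_positions(self) -> np.ndarray:
        """Channel offsets ``s`` on the virtual detector, centered on 0."""
        k = np.arange(self.n_det, dtype=np.float64)
        return (k - (self.n_det - 1) / 2.0) * self.pitch_iso

    def view_angles(self) -> np.ndarray:
        return self.angle_start + 2.0 * np.pi * np.arange(self.n_views) / self.n_views

    def fov_radius(self, s_edge: float | None = None) -> float:
        """Scan FOV radius: closest approach to the isocenter of the most
        lateral retained ray (``s_edge`` defaults to the full detector)."""
        if s_edge is None:
            s_edge = float(np.max(np.abs(self.channel_positions())))
        sid = self.source_iso
        return sid * s_edge / math.hypot(sid, s_edge)

    @classmethod
    def default_for(
        cls,
        image_size: int,
        pixel_size: float = 1.0,
        out_size: int | None = None,
        n_views: int = 720,
    ) -> "FanGeometry":
        """Diagnostic-CT-like fan for a square image of ``image_size`` pixels.

        Source-to-isocenter distance is twice the image's physical diagonal
        (mild fan angle); the untruncated detector covers a FOV disk of
        radius half the image side, i.e. a body kept within a 5% border
        margin is covered with >10% headroom.
        """
        out_size = out_size if out_size is not None else image_size
        extent = image_size * pixel_size
        sid = 2.0 * extent * math.sqrt(2.0)
        r_fov = 0.5 * extent
        n_det = int(math.ceil(1.5 * out_size))
        # place channel endpoints so the edge ray grazes the FOV disk
        s_max = sid * r_fov / math.sqrt(sid * sid - r_fov * r_fov)
        pitch_iso = 2.0 * s_max / (n_det - 1)
        return cls(
            n_views=n_views,
            source_iso=sid,
            iso_det=sid,
            n_det=n_det,
            det_pitch=pitch_iso * 2.0,  # magnification is 2 with iso_det == source_iso
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FanGeometry":
        return cls(**d)


@dataclass
class Sinogram:
    """Fan-beam line integrals with an explicit record of retained channels.

    ``values`` has one column per *retained* channel; truncated channels are
    deleted outright, so nothing downstream can mistake them for measured
    zeros.  ``retained`` is the inclusive ``(first, last)`` absolute channel
    index range still present.
    """

    values: np.ndarray
    geometry: FanGeometry
    retained: tuple[int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("sinogram must be 2D (views x channels)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")
        first, last = self.retained
        if not (0 <= first <= last < self.geometry.n_det):
            raise ValueError("retained range outside [0, n_det)")
        if self.values.shape != (self.geometry.n_views, last - first + 1):
            raise ValueError("values shape inconsistent with geometry/retained")

    @property
    def n_retained(self) -> int:
        return self.retained[1] - self.retained[0] + 1

    @property
    def is_truncated(self) -> bool:
        return self.n_retained < self.geometry.n_det

    def retained_positions(self) -> np.ndarray:
        s = self.geometry.channel_positions()
        return s[self.retained[0] : self.retained[1] + 1]

    def fov_radius(self) -> float:
        s = self.retained_positions()
        return self.geometry.fov_radius(float(min(abs(s[0]), abs(s[-1]))))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.values)
        meta = {"geometry": self.geometry.to_dict(), "retained": list(self.retained)}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "Sinogram":
        path = Path(path)
        values = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(values, FanGeometry.from_dict(meta["geometry"]), tuple(meta["retained"]))


# ---------------------------------------------------------------------
# forward projection
# ---------------------------------------------------------------------

@njit(cache=True)
def _fan_project_kernel(img, px, cx, sid, angles, s_pos, r_img, step):  # pragma: no cover - jit
    n_views = angles.shape[0]
    n_det = s_pos.shape[0]
    n_steps = int(math.ceil(2.0 * r_img / step)) + 1
    dt = 2.0 * r_img / (n_steps - 1)
    h = img.shape[0]
    out = np.zeros((n_views, n_det))
    for v in range(n_views):
        cb = math.cos(angles[v])
        sb = math.sin(angles[v])
        srcx = -sid * cb
        srcy = -sid * sb
        for d in range(n_det):
            detx = -s_pos[d] * sb
            dety = s_pos[d] * cb
            dx = detx - srcx
            dy = dety - srcy
            inv_len = 1.0 / math.sqrt(dx * dx + dy * dy)
            ux = dx * inv_len
            uy = dy * inv_len
            tc = -(srcx * ux + srcy * uy)  # closest approach to isocenter
            acc = 0.0
            for k in range(n_steps):
                t = tc - r_img + k * dt
                x = srcx + t * ux
                y = srcy + t * uy
                col = x / px + cx
                row = y / px + cx
                c0 = int(math.floor(col))
                r0 = int(math.floor(row))
                if c0 < -1 or c0 > h - 1 or r0 < -1 or r0 > h - 1:
                    continue
                fc = col - c0
                fr = row - r0
                v00 = img[r0, c0] if (0 <= r0 < h and 0 <= c0 < h) else 0.0
                v01 = img[r0, c0 + 1] if (0 <= r0 < h and 0 <= c0 + 1 < h) else 0.0
                v10 = img[r0 + 1, c0] if (0 <= r0 + 1 < h and 0 <= c0 < h) else 0.0
                v11 = img[r0 + 1, c0 + 1] if (0 <= r0 + 1 < h and 0 <= c0 + 1 < h) else 0.0
                acc += (1 - fr) * ((1 - fc) * v00 + fc * v01) + fr * ((1 - fc) * v10 + fc * v11)
            out[v, d] = acc * dt
    return out


def forward_project(image: ImageGrid, geom: FanGeometry, step_frac: float = 0.5) -> Sinogram:
    """Fan-beam forward projection by sampled line integration.

    Each sinogram value is the line integral of the image along the
    source-to-channel ray, computed with bilinear sampling at a step of
    ``step_frac`` pixels and weighted by the step length.  Rays are sampled
    uniformly around their closest approach to the isocenter over the
    circumscribed radius of the image; samples outside the grid contribute
    zero.
    """
    if not image.is_square:
        raise ValueError("forward projection expects a square image")
    if geom.fov_radius() < 0.45 * image.physical_extent - 1e-9:
        raise ValueError("detector FOV does not cover the object support")

    px = image.pixel_size
    cx = (image.pixels.shape[0] - 1) / 2.0
    r_img = 0.5 * image.physical_extent * math.sqrt(2.0) + 2 * px
    values = _fan_project_kernel(
        image.pixels.astype(np.float64),
        px,
        cx,
        geom.source_iso,
        geom.view_angles(),
        geom.channel_positions(),
        r_img,
        step_frac * px,
    )
    return Sinogram(values, geom, (0, geom.n_det - 1))


# ---------------------------------------------------------------------
# truncation
# ---------------------------------------------------------------------

def truncate_sinogram(sino: Sinogram, ratio: float) -> Sinogram:
    """Delete lateral channels, keeping the central ``(1 - ratio)`` fraction.

    ``ratio`` is the total fraction of channels removed (split evenly
    between the two sides).  Removed channels are deleted, not zeroed, so
    downstream consumers cannot silently treat them as data.
    """
    if not (0.0 <= ratio < 1.0):
        raise ValueError("truncation ratio must be in [0, 1)")
    n_det = sino.geometry.n_det
    n_keep = int(round((1.0 - ratio) * n_det))
    if n_keep < 8:
        raise ValueError("fewer than 8 channels would remain after truncation")
    first = (n_det - n_keep) // 2
    last = first + n_keep - 1
    cur_first, cur_last = sino.retained
    if first < cur_first or last > cur_last:
        raise ValueError("requested retention exceeds channels still present")
    vals = sino.values[:, first - cur_first : last - cur_first + 1]
    return Sinogram(vals.copy(), sino.geometry, (first, last))


# ---------------------------------------------------------------------
# filtered backprojection
# ---------------------------------------------------------------------

def _ramp_kernel(n: int, ds: float) -> np.ndarray:
    """Band-limited spatial Ram-Lak kernel on offsets ``-(n-1)..(n-1)``."""
    k = np.arange(-(n - 1), n)
    h = np.zeros(k.shape, dtype=np.float64)
    h[k == 0] = 1.0 / (4.0 * ds * ds)
    odd = (k % 2) != 0
    h[odd] = -1.0 / (np.pi * np.pi * k[odd].astype(np.float64) ** 2 * ds * ds)
    return h


def _filter_rows(p: np.ndarray, ds: float) -> np.ndarray:
    """Convolve every sinogram row with the ramp kernel (FFT, 'same' part)."""
    n = p.shape[1]
    h = _ramp_kernel(n, ds)
    size = int(2 ** math.ceil(math.log2(len(h) + n)))
    H = np.fft.rfft(h, size)
    P = np.fft.rfft(p, size, axis=1)
    conv = np.fft.irfft(P * H[None, :], size, axis=1)
    # the 1/2 is the full-scan fan-beam filter normalization (every ray is
    # measured twice over a 2*pi rotation)
    return conv[:, n - 1 : 2 * n - 1] * ds * 0.5


def backproject(
    q: np.ndarray,
    geom: FanGeometry,
    retained: tuple[int, int],
    out_size: int,
    pixel_size: float,
    weight: str = "fbp",
) -> np.ndarray:
    """Pixel-driven fan-beam backprojection of per-view profiles ``q``.

    ``weight='fbp'`` applies the ``SID^2/(SID+u)^2`` distance weighting and
    the ``d_beta`` view measure (exact FBP backprojection); ``weight='mean'``
    is the plain average over views used by the iterative solver.
    """
    sid = geom.source_iso
    s_all = geom.channel_positions()
    s = s_all[retained[0] : retained[1] + 1]
    angles = geom.view_angles()
    half = (out_size - 1) / 2.0
    idx = (np.arange(out_size) - half) * pixel_size
    X, Y = np.meshgrid(idx, idx)  # X: cols, Y: rows
    out = np.zeros((out_size, out_size), dtype=np.float64)
    dbeta = 2.0 * np.pi / geom.n_views
    for i, beta in enumerate(angles):
        cb, sb = math.cos(beta), math.sin(beta)
        u = X * cb + Y * sb
        v = -X * sb + Y * cb
        denom = sid + u
        s_prime = sid * v / denom
        vals = np.interp(s_prime, s, q[i], left=0.0, right=0.0)
        if weight == "fbp":
            out += dbeta * (sid * sid) / (denom * denom) * vals
        else:
            out += vals / geom.n_views
    return out


def fbp_reconstruct(sino: Sinogram, out_size: int) -> ImageGrid:
    """Ramp-filtered fan-beam backprojection onto the retained FOV.

    The output grid is a square of ``out_size`` pixels whose side equals the
    diameter of the retained scan FOV disk, so truncated reconstructions
    automatically zoom to the interior region that the remaining rays cover.
    """
    if out_size < 16:
        raise ValueError("out_size must be at least 16")
    if sino.n_retained < 2:
        raise ValueError("empty retained range")
    sid = sino.geometry.source_iso
    s = sino.retained_positions()
    ds = sino.geometry.pitch_iso
    pre = sid / np.sqrt(sid * sid + s * s)
    q = _filter_rows(sino.values * pre[None, :], ds)
    r_fov = sino.fov_radius()
    px = 2.0 * r_fov / out_size
    recon = backproject(q, sino.geometry, sino.retained, out_size, px, weight="fbp")
    return ImageGrid(recon.astype(np.float32), pixel_size=px, value_range=(0.0, max(1.0, float(recon.max()))))


# ---------------------------------------------------------------------
# paired simulation
# ---------------------------------------------------------------------

def resample_to_recon_grid(
    phantom: ImageGrid, geom: FanGeometry, ratio: float, out_size: int
) -> ImageGrid:
    """Resample the phantom onto the reconstruction grid of a given
    truncation ratio, so simulated pairs are pixel-aligned."""
    n_det = geom.n_det
    n_keep = int(round((1.0 - ratio) * n_det))
    first = (n_det - n_keep) // 2
    last = first + n_keep - 1
    s_all = geom.channel_positions()
    s_edge = float(min(abs(s_all[first]), abs(s_all[last])))
    r_fov = geom.fov_radius(s_edge)
    px = 2.0 * r_fov / out_size
    half = (out_size - 1) / 2.0
    idx = (np.arange(out_size) - half) * px
    X, Y = np.meshgrid(idx, idx)
    cx = (phantom.pixels.shape[0] - 1) / 2.0
    cols = X / phantom.pixel_size + cx
    rows = Y / phantom.pixel_size + cx
    vals = map_coordinates(phantom.pixels.astype(np.float64), [rows, cols], order=1, cval=0.0, prefilter=False)
    return ImageGrid(vals.astype(np.float32), pixel_size=px, value_range=phantom.value_range)


def simulate_truncated_pair(
    phantom: ImageGrid, geom: FanGeometry, ratio: float, out_size: int
) -> tuple[ImageGrid, ImageGrid]:
    """Produce one pixel-aligned (artifact, reference) pair.

    ``artifact`` is the FBP reconstruction of the truncated projections;
    ``reference`` is the phantom itself resampled onto the same grid.
    """
    sino = forward_project(phantom, geom)
    if ratio > 0:
        sino = truncate_sinogram(sino, ratio)
    artifact = fbp_reconstruct(sino, out_size)
    reference = resample_to_recon_grid(phantom, geom, ratio, out_size)
    reference = ImageGrid(reference.pixels, artifact.pixel_size, phantom.value_range)
    return artifact, reference
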