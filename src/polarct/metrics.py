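"""Image quality metrics and cupping diagnostics.

PSNR is peak-referenced: ``20 log10( sqrt(M N) * max|f_gt| / ||f_gt - f_p||_2 )``,
which is algebraically the usual ``20 log10( MAX / sqrt(MSE) )``.

SSIM defaults to the global-statistics form (one mean/variance/covariance
over the whole evaluation region) with stabilizers ``c_i = (k_i L)^2``,
``k1 = k2 = 0.03`` and ``L`` the maximum pixel value of the reference; note
the common library convention is ``k1 = 0.01``, available via the ``k1``
argument.  A windowed (11x11 Gaussian) mode backed by scikit-image is
provided for cross-checking.

Metrics operate on physical-value images and are restricted to the
inscribed FOV circle by default, since FOV-limited CT images carry no
signal in the corners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ImageGrid

__all__ = [
    "MetricReport",
    "psnr",
    "ssim",
    "radial_bias_profile",
    "line_profile",
    "fov_mask",
    "evaluate_pairs",
]


def _as_array(img) -> np.ndarray:
    return img.pixels.astype(np.float64) if isinstance(img, ImageGrid) else np.asarray(img, dtype=np.float64)


def fov_mask(shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the inscribed circle of a square grid."""
    h, w = shape
    if h != w:
        raise ValueError("FOV mask expects a square image")
    half = (h - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    return np.hypot(xx - half, yy - half) <= half


def psnr(f_gt, f_p, mask: np.ndarray | None = None) -> float:
    """Peak signal-to-noise ratio in dB, peak = max|f_gt|.

    Identical images give ``inf``; an all-zero reference is undefined.
    """
    a, b = _as_array(f_gt), _as_array(f_p)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if mask is not None:
        a, b = a[mask], b[mask]
    peak = np.abs(a).max()
    if peak == 0:
        raise ValueError("PSNR undefined for an all-zero reference")
    err = np.linalg.norm(a - b)
    if err == 0:
        return float("inf")
    return float(20.0 * np.log10(np.sqrt(a.size) * peak / err))


def ssim(
    f_gt,
    f_p,
    mask: np.ndarray | None = None,
    k1: float = 0.03,
    k2: float = 0.03,
    data_range: float | None = None,
    windowed: bool = False,
) -> float:
    """Structural similarity between a reference and an estimate.

    Default is the global-statistics form; ``windowed=True`` computes the
    conventional 11x11-Gaussian local SSIM (scikit-image) instead, as an
    independent cross-check.
    """
    a, b = _as_array(f_gt), _as_array(f_p)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    L = data_range if data_range is not None else float(a.max())
    if L <= 0:
        L = max(float(np.abs(a).max()), 1e-12)
    if windowed:
        from skimage.metrics import structural_similarity

        full = structural_similarity(
            a, b, data_range=L, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=k1, K2=k2, full=True,
        )[1]
        return float(full[mask].mean()) if mask is not None else float(full.mean())
    if mask is not None:
        a, b = a[mask], b[mask]
    c1 = (k1 * L) ** 2
    c2 = (k2 * L) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(
        (2 * mu_a * mu_b + c1) * (2 * cov + c2)
        / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
    )


def radial_bias_profile(est, ref, n_bins: int = 10) -> np.ndarray:
    """Mean residual (est - ref) in equal-width concentric annuli.

    The cupping artifact shows up as a profile that rises from the center
    to the FOV edge.  Bins cover the inscribed circle.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 annuli")
    a, r = _as_array(est), _as_array(ref)
    if a.shape != r.shape or a.shape[0] != a.shape[1]:
        raise ValueError("images must be square and same shape")
    h = a.shape[0]
    half = (h - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:h]
    rho = np.hypot(xx - half, yy - half) / half
    res = a - r
    out = np.empty(n_bins)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    for i in range(n_bins):
        sel = (rho >= edges[i]) & (rho < edges[i + 1])
        out[i] = res[sel].mean()
    return out


def line_profile(image, axis: str, index: int) -> np.ndarray:
    """Pixel values along one row or column, for profile plots."""
    a = _as_array(image)
    if axis not in ("row", "col"):
        raise ValueError("axis must be 'row' or 'col'")
    n = a.shape[0] if axis == "row" else a.shape[1]
    if not (0 <= index < n):
        raise IndexError("profile index out of range")
    return a[index, :].copy() if axis == "row" else a[:, index].copy()


@dataclass
class MetricReport:
    """Per-image PSNR/SSIM records with aggregates."""

    rows: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def mean_ssim(self) -> float:
        return float(self.rows["ssim"].mean())

    @property
    def median_ssim(self) -> float:
        return float(self.rows["ssim"].median())

    @property
    def mean_psnr(self) -> float:
        return float(self.rows["psnr"].mean())

    @property
    def median_psnr(self) -> float:
        return float(self.rows["psnr"].median())

    def summary(self) -> pd.DataFrame:
        return self.rows[["ssim", "psnr"]].agg(["mean", "median", "std"])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.metadata.items():
                fh.write(f"# {k}: {v}\n")
            self.rows.to_csv(fh, index=False)
            fh.write(f"# mean_ssim: {self.mean_ssim}\n# mean_psnr: {self.mean_psnr}\n")


def evaluate_pairs(pairs, restrict_fov: bool = True, metadata: dict | None = None) -> MetricReport:
    """Score a sequence of ``(id, estimate, reference)`` image triples."""
    records = []
    for pair_id, est, ref in pairs:
        mask = fov_mask(_as_array(ref).shape) if restrict_fov else None
        records.append({
            "id": pair_id,
            "ssim": ssim(ref, est, mask=mask),
            "psnr": psnr(ref, est, mask=mask),
        })
    return MetricReport(pd.DataFrame.from_records(records), metadata or {})
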