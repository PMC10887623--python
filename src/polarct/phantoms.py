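"""Seeded generators for ellipse phantoms and unpaired training datasets.

The study conditions call for unpaired sets of artifact-affected and
artifact-free images.  Since no clinical data ships with the package, a
seeded ellipse-phantom family stands in: one smooth outer body ellipse of
water-like attenuation containing a number of random interior ellipses.
Piecewise-constant anatomy is deliberate — it matches the assumption under
which the total-variation baseline is expected to work.

The train split is genuinely unpaired (artifact and clean images come from
disjoint phantom seeds); only the test split retains ground-truth pairing,
which is used for evaluation and never for training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import ImageGrid

__all__ = ["PhantomSpec", "DatasetManifest", "ManifestEntry", "make_ellipse_phantom", "build_unpaired_dataset"]


@dataclass
class PhantomSpec:
    """Parameters of one random ellipse phantom.

    ``body_axes`` are the semi-axes of the outer body ellipse relative to the
    half side of the grid; a value of 0.9 places the body edge at 90% of the
    half-side, i.e. a 5% margin to the grid border.  Inclusion contrasts are
    drawn uniformly from ``contrast_range`` and added to the body value.
    """

    seed: int = 0
    size: int = 128
    n_inclusions: int = 5
    # the body nearly fills the grid: truncation scans are interior scans,
    # so the object must extend well beyond the retained FOV on all sides
    body_axes: tuple[float, float] = (0.9, 0.84)
    contrast_range: tuple[float, float] = (-0.5, 1.0)
    body_value: float = 1.0
    smooth_sigma: float = 0.5
    value_max: float = 2.0

    def __post_init__(self) -> None:
        if self.size < 16:
            raise ValueError("phantom size must be at least 16")
        if self.n_inclusions < 0:
            raise ValueError("n_inclusions must be nonnegative")
        lo, hi = self.contrast_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError("contrast_range must be finite and ordered")
        if not (0 < max(self.body_axes) <= 0.9):
            raise ValueError("body must keep a margin of at least 5% of the side")

    def with_seed(self, seed: int) -> "PhantomSpec":
        return PhantomSpec(**{**asdict(self), "seed": seed})


def _ellipse_mask(size: int, cx: float, cy: float, a: float, b: float, theta: float) -> np.ndarray:
    """Boolean mask of an ellipse in pixel coordinates (a, b in pixels)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    x = xx - cx
    y = yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (x * ct + y * st) / a
    v = (-x * st + y * ct) / b
    return u * u + v * v <= 1.0


def make_ellipse_phantom(spec: PhantomSpec) -> ImageGrid:
    """Generate one random ellipse phantom, deterministic given ``spec.seed``.

    The outer body ellipse has value ``body_value``; each interior ellipse
    adds a uniform random contrast, clipped to the body support and clamped
    to ``[0, value_max]``.  An optional Gaussian smoothing (default sigma
    0.5 px) band-limits the edges so analytic reconstruction behaves well.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    half = (size - 1) / 2.0

    # body ellipse: jittered semi-axes and a random orientation
    ax = spec.body_axes[0] * half * rng.uniform(0.92, 1.0)
    bx = spec.body_axes[1] * half * rng.uniform(0.92, 1.0)
    theta0 = rng.uniform(0, np.pi)
    body = _ellipse_mask(size, half, half, ax, bx, theta0)

    img = np.zeros((size, size), dtype=np.float64)
    img[body] = spec.body_value

    for _ in range(spec.n_inclusions):
        # center inside the body, semi-axes a fraction of the body's
        r = np.sqrt(rng.uniform(0.0, 0.55))
        ang = rng.uniform(0, 2 * np.pi)
        cx = half + r * ax * np.cos(ang)
        cy = half + r * bx * np.sin(ang)
        a = rng.uniform(0.06, 0.3) * ax
        b = rng.uniform(0.06, 0.3) * bx
        th = rng.uniform(0, np.pi)
        contrast = rng.uniform(*spec.contrast_range)
        mask = _ellipse_mask(size, cx, cy, a, b, th) & body
        img[mask] += contrast

    img = np.clip(img, 0.0, spec.value_max)
    if spec.smooth_sigma > 0:
        img = gaussian_filter(img, spec.smooth_sigma)
        img = np.clip(img, 0.0, spec.value_max)
    return ImageGrid(img.astype(np.float32), pixel_size=1.0, value_range=(0.0, spec.value_max))


@dataclass
class ManifestEntry:
    id: str
    role: str  # artifact | clean | reference
    path: str
    seed: int


@dataclass
class DatasetManifest:
    """On-disk index of a simulated unpaired dataset."""

    root: str
    entries: list[ManifestEntry] = field(default_factory=list)
    split: dict = field(default_factory=dict)  # extra provenance (specs, geometry, ratio)

    def __post_init__(self) -> None:
        ids = [(e.id, e.role) for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate (id, role) entries in manifest")

    def by_role(self, role: str, split: str | None = None) -> list[ManifestEntry]:
        out = [e for e in self.entries if e.role == role]
        if split is not None:
            out = [e for e in out if e.id.startswith(split)]
        return out

    def load_image(self, entry: ManifestEntry) -> ImageGrid:
        return ImageGrid.load(Path(self.root) / entry.path)

    def save(self, path: str | Path | None = None) -> Path:
        path = Path(path) if path is not None else Path(self.root) / "manifest.json"
        payload = {
            "root": str(self.root),
            "entries": [asdict(e) for e in self.entries],
            "split": self.split,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        if path.is_dir():
            path = path / "manifest.json"
        payload = json.loads(path.read_text())
        entries = [ManifestEntry(**e) for e in payload["entries"]]
        return cls(root=payload["root"], entries=entries, split=payload.get("split", {}))


def build_unpaired_dataset(
    n_train: int,
    n_test: int,
    spec: PhantomSpec,
    geometry=None,
    ratio: float = 0.3,
    out_dir: str | Path = "dataset",
    out_size: int | None = None,
    seed: int = 0,
) -> DatasetManifest:
    """Simulate an unpaired truncation-artifact dataset and write it to disk.

    Train split: ``n_train`` artifact-affected reconstructions and ``n_train``
    artifact-free images drawn from disjoint phantom seeds.  Test split:
    ``n_test`` artifact images, each stored together with its same-phantom
    reference (the phantom resampled onto the reconstruction grid).

    All phantom seeds are derived from ``seed`` and recorded in the manifest,
    so every image on disk can be regenerated bit-for-bit.
    """
    from .ctsim import FanGeometry, simulate_truncated_pair, resample_to_recon_grid

    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must both be at least 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    out_size = out_size if out_size is not None else spec.size
    if geometry is None:
        geometry = FanGeometry.default_for(spec.size, out_size=out_size)

    # disjoint seed blocks per role, all below 2**31
    base = int(seed) % (2**28)
    art_seeds = [base * 8 + 1 + 8 * i for i in range(n_train)]
    clean_seeds = [base * 8 + 3 + 8 * i for i in range(n_train)]
    test_seeds = [base * 8 + 5 + 8 * i for i in range(n_test)]

    entries: list[ManifestEntry] = []

    def _write(img: ImageGrid, name: str) -> str:
        rel = f"images/{name}"
        img.save(out_dir / rel)
        return rel

    for i, s in enumerate(art_seeds):
        phantom = make_ellipse_phantom(spec.with_seed(s))
        artifact, _ = simulate_truncated_pair(phantom, geometry, ratio, out_size)
        entries.append(ManifestEntry(f"train_art_{i:04d}", "artifact", _write(artifact, f"train_art_{i:04d}"), s))
    for i, s in enumerate(clean_seeds):
        phantom = make_ellipse_phantom(spec.with_seed(s))
        clean = resample_to_recon_grid(phantom, geometry, ratio, out_size)
        entries.append(ManifestEntry(f"train_cln_{i:04d}", "clean", _write(clean, f"train_cln_{i:04d}"), s))
    for i, s in enumerate(test_seeds):
        phantom = make_ellipse_phantom(spec.with_seed(s))
        artifact, reference = simulate_truncated_pair(phantom, geometry, ratio, out_size)
        entries.append(ManifestEntry(f"test_{i:04d}", "artifact", _write(artifact, f"test_art_{i:04d}"), s))
        entries.append(ManifestEntry(f"test_{i:04d}", "reference", _write(reference, f"test_ref_{i:04d}"), s))

    manifest = DatasetManifest(
        root=str(out_dir),
        entries=entries,
        split={
            "phantom_spec": asdict(spec),
            "geometry": geometry.to_dict(),
            "ratio": ratio,
            "out_size": out_size,
            "seed": int(seed),
        },
    )
    manifest.save()
    return manifest
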