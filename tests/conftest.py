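"""Shared fixtures: analytic disk phantoms, fan geometries, tiny datasets.

Everything is generated programmatically and seeded; the expensive objects
(720-view sinograms, small training datasets) are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from polarct import (
    FanGeometry,
    ImageGrid,
    PhantomSpec,
    build_unpaired_dataset,
    forward_project,
)

DISK_SIZE = 128
DISK_RADIUS = 40.0
BODY_RADIUS = 52.0  # nearly fills the FOV, like a patient larger than the scan FOV


def make_disk(size: int, radius: float, value: float = 1.0, sigma: float = 0.8) -> ImageGrid:
    half = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    disk = (np.hypot(xx - half, yy - half) <= radius).astype(np.float64) * value
    if sigma > 0:
        disk = gaussian_filter(disk, sigma)
    return ImageGrid(disk.astype(np.float32), value_range=(0.0, value))


@pytest.fixture(scope="session")
def disk_image() -> ImageGrid:
    """Smoothed centered disk, radius 40 px on a 128 px grid."""
    return make_disk(DISK_SIZE, DISK_RADIUS)


@pytest.fixture(scope="session")
def body_disk_image() -> ImageGrid:
    """A disk large enough that 30% truncation cuts into it."""
    return make_disk(DISK_SIZE, BODY_RADIUS)


@pytest.fixture(scope="session")
def geom128() -> FanGeometry:
    return FanGeometry.default_for(DISK_SIZE)


@pytest.fixture(scope="session")
def disk_sinogram(disk_image, geom128):
    return forward_project(disk_image, geom128)


@pytest.fixture(scope="session")
def body_sinogram(body_disk_image, geom128):
    return forward_project(body_disk_image, geom128)


@pytest.fixture(scope="session")
def phantom_spec64() -> PhantomSpec:
    return PhantomSpec(seed=0, size=64, n_inclusions=5)


@pytest.fixture(scope="session")
def tiny_manifest(tmp_path_factory, phantom_spec64):
    """Small unpaired dataset: 6 train images per domain, 2 test pairs."""
    out = tmp_path_factory.mktemp("dataset")
    geom = FanGeometry.default_for(64, n_views=240)
    return build_unpaired_dataset(6, 2, phantom_spec64, geom, ratio=0.3,
                                  out_dir=out, out_size=64, seed=5)
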