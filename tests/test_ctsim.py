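"""Fan-beam projection, truncation, and FBP physics checks.

The analytic disk phantom is the oracle: chord lengths through a disk are
known in closed form, and FBP of complete data must recover the density.
"""

import numpy as np
import pytest
from dataclasses import replace

from polarct import (
    FanGeometry,
    ImageGrid,
    Sinogram,
    fbp_reconstruct,
    forward_project,
    simulate_truncated_pair,
    truncate_sinogram,
)
from polarct.ctsim import resample_to_recon_grid
from polarct.metrics import fov_mask, radial_bias_profile, ssim

from conftest import DISK_RADIUS, DISK_SIZE, make_disk


def interior_mask(size, radius_px, margin_px=2.0):
    half = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return np.hypot(xx - half, yy - half) < radius_px - margin_px


class TestForwardProjection:
    def test_zero_image_projects_to_zero(self, geom128):
        img = ImageGrid(np.zeros((DISK_SIZE, DISK_SIZE), np.float32))
        sino = forward_project(img, geom128)
        assert np.all(sino.values == 0.0)

    def test_central_chord_length(self, geom128):
        """The ray through the center of a unit disk has line integral 2r."""
        # odd channel count puts one channel exactly on the central ray
        geom = replace(geom128, n_det=geom128.n_det + 1, n_views=48)
        disk = make_disk(DISK_SIZE, DISK_RADIUS, sigma=0.0)
        sino = forward_project(disk, geom)
        s = geom.channel_positions()
        central = np.argmin(np.abs(s))
        assert abs(s[central]) < 1e-9
        chords = sino.values[:, central]
        assert np.all(np.abs(chords - 2 * DISK_RADIUS) / (2 * DISK_RADIUS) < 0.01)

    def test_linearity(self, geom128):
        rng = np.random.default_rng(0)
        a = ImageGrid(rng.uniform(0, 1, (64, 64)).astype(np.float32))
        b = ImageGrid(rng.uniform(0, 1, (64, 64)).astype(np.float32))
        geom = FanGeometry.default_for(64, n_views=32)
        pa = forward_project(a, geom).values
        pb = forward_project(b, geom).values
        pab = forward_project(ImageGrid(a.pixels + b.pixels), geom).values
        np.testing.assert_allclose(pab, pa + pb, rtol=1e-5, atol=1e-5)

    def test_nonnegative_for_nonnegative_image(self, disk_sinogram):
        assert disk_sinogram.values.min() >= 0.0

    def test_geometry_must_cover_object(self):
        img = ImageGrid(np.ones((64, 64), np.float32))
        geom = FanGeometry.default_for(32, n_views=16)  # FOV for a 32 px image
        with pytest.raises(ValueError):
            forward_project(img, geom)


class TestTruncation:
    def test_ratio_zero_is_identity(self, disk_sinogram):
        out = truncate_sinogram(disk_sinogram, 0.0)
        assert out.retained == disk_sinogram.retained
        assert np.array_equal(out.values, disk_sinogram.values)

    def test_channel_arithmetic(self):
        geom = FanGeometry(n_views=4, n_det=1000)
        sino = Sinogram(np.zeros((4, 1000)), geom, (0, 999))
        out = truncate_sinogram(sino, 0.3)
        assert out.n_retained == 700
        assert out.retained == (150, 849)  # centered

    def test_truncation_removes_outer_chords(self, body_sinogram):
        """At 50% truncation of a body-sized disk, every view discards
        genuinely measured outer chords (deleted channels were nonzero)."""
        out = truncate_sinogram(body_sinogram, 0.5)
        first, last = out.retained
        deleted = np.concatenate([body_sinogram.values[:, :first],
                                  body_sinogram.values[:, last + 1 :]], axis=1)
        assert deleted.shape[1] > 0
        # each view loses nonzero line integrals ...
        assert np.all(deleted.max(axis=1) > 0.1)
        # ... so the retained data sums to strictly less than the full data
        assert np.all(out.values.sum(axis=1) < body_sinogram.values.sum(axis=1))

    @pytest.mark.parametrize("ratio", [1.0, 1.5, -0.1])
    def test_invalid_ratio(self, disk_sinogram, ratio):
        with pytest.raises(ValueError):
            truncate_sinogram(disk_sinogram, ratio)

    def test_overly_aggressive_truncation_rejected(self):
        geom = FanGeometry(n_views=4, n_det=16)
        sino = Sinogram(np.zeros((4, 16)), geom, (0, 15))
        with pytest.raises(ValueError):
            truncate_sinogram(sino, 0.99)


class TestFBP:
    def test_zero_sinogram_reconstructs_to_zero(self, geom128):
        sino = Sinogram(np.zeros((geom128.n_views, geom128.n_det)), geom128,
                        (0, geom128.n_det - 1))
        rec = fbp_reconstruct(sino, 64)
        assert np.all(rec.pixels == 0.0)

    def test_untruncated_disk_interior_accuracy(self, disk_image, disk_sinogram, geom128):
        rec = fbp_reconstruct(disk_sinogram, DISK_SIZE)
        ref = resample_to_recon_grid(disk_image, geom128, 0.0, DISK_SIZE)
        mask = interior_mask(DISK_SIZE, DISK_RADIUS / rec.pixel_size)
        rmse = np.sqrt(((rec.pixels - ref.pixels)[mask] ** 2).mean())
        assert rmse < 0.05  # < 5% of the disk density (mu = 1)

    def test_truncation_produces_cupping(self, body_sinogram, body_disk_image, geom128):
        """The radial bias profile rises from center to FOV edge."""
        rec = fbp_reconstruct(truncate_sinogram(body_sinogram, 0.3), DISK_SIZE)
        ref = resample_to_recon_grid(body_disk_image, geom128, 0.3, DISK_SIZE)
        profile = radial_bias_profile(rec, ref, n_bins=10)
        assert profile[-1] > profile[0]

    def test_cupping_monotone_in_truncation_ratio(self, body_sinogram, body_disk_image, geom128):
        biases = []
        for ratio in (0.3, 0.5):
            rec = fbp_reconstruct(truncate_sinogram(body_sinogram, ratio), DISK_SIZE)
            ref = resample_to_recon_grid(body_disk_image, geom128, ratio, DISK_SIZE)
            biases.append(radial_bias_profile(rec, ref, n_bins=10)[-1])
        assert biases[1] >= biases[0]


class TestSimulatedPairs:
    def test_no_truncation_pair_is_consistent(self, phantom_spec64):
        from polarct import make_ellipse_phantom

        phantom = make_ellipse_phantom(phantom_spec64)
        geom = FanGeometry.default_for(64, n_views=240)
        artifact, reference = simulate_truncated_pair(phantom, geom, 0.0, 64)
        mask = fov_mask((64, 64))
        rmse = np.sqrt(((artifact.pixels - reference.pixels)[mask] ** 2).mean())
        assert rmse < 0.05 * reference.pixels.max()

    def test_truncated_pair_less_similar_than_untruncated(self, phantom_spec64):
        from polarct import make_ellipse_phantom

        phantom = make_ellipse_phantom(phantom_spec64.with_seed(4))
        geom = FanGeometry.default_for(64, n_views=240)
        art, ref = simulate_truncated_pair(phantom, geom, 0.3, 64)
        clean, ref0 = simulate_truncated_pair(phantom, geom, 0.0, 64)
        mask = fov_mask((64, 64))
        assert ssim(ref, art, mask=mask) < ssim(ref0, clean, mask=mask)

    def test_reference_is_resampled_phantom(self, phantom_spec64):
        from polarct import make_ellipse_phantom

        phantom = make_ellipse_phantom(phantom_spec64.with_seed(2))
        geom = FanGeometry.default_for(64, n_views=16)
        _, reference = simulate_truncated_pair(phantom, geom, 0.0, 64)
        # untruncated FOV radius equals half the phantom side here, so the
        # reference grid is the phantom grid: values match exactly
        np.testing.assert_allclose(reference.pixels, phantom.pixels, atol=1e-6)

    def test_pair_grids_are_aligned(self, phantom_spec64):
        from polarct import make_ellipse_phantom

        phantom = make_ellipse_phantom(phantom_spec64.with_seed(3))
        geom = FanGeometry.default_for(64, n_views=240)
        art, ref = simulate_truncated_pair(phantom, geom, 0.3, 64)
        assert art.shape == ref.shape
        assert art.pixel_size == pytest.approx(ref.pixel_size)


class TestSinogramIO:
    def test_save_load_roundtrip(self, tmp_path, disk_sinogram):
        disk_sinogram.save(tmp_path / "sino")
        back = Sinogram.load(tmp_path / "sino")
        assert np.array_equal(back.values, disk_sinogram.values)
        assert back.retained == disk_sinogram.retained
        assert back.geometry.n_views == disk_sinogram.geometry.n_views
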