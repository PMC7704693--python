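"""Forward projection and fan-to-parallel rebinning."""

import numpy as np
import pytest

from kwia.geometry import (
    ProjectionGeometry,
    Sinogram,
    forward_project_parallel,
    rebin_fan_to_parallel,
)

from conftest import make_disk


def ray_march_project(image, pixel_spacing, geometry, step_px=0.1):
    """Brute-force ray-marching line integrals (independent oracle)."""
    n = image.shape[0]
    c = (n - 1) / 2.0
    t = geometry.detector_offsets / pixel_spacing
    angles = np.arange(geometry.n_parallel_views) * np.pi / geometry.n_parallel_views
    # sample points along each ray at fine steps
    half_len = n / np.sqrt(2.0) + 2
    u = np.arange(-half_len, half_len, step_px)
    out = np.empty((angles.size, t.size))
    for v, theta in enumerate(angles):
        ct, st = np.cos(theta), np.sin(theta)
        x = t[:, None] * ct - u[None, :] * st + c
        y = t[:, None] * st + u[None, :] * ct + c
        x0 = np.floor(x).astype(int)
        y0 = np.floor(y).astype(int)
        fx = x - x0
        fy = y - y0
        acc = np.zeros(t.size)
        for dx, wx in ((0, 1 - fx), (1, fx)):
            for dy, wy in ((0, 1 - fy), (1, fy)):
                xi = x0 + dx
                yi = y0 + dy
                ok = (xi >= 0) & (xi < n) & (yi >= 0) & (yi < n)
                acc += np.where(ok, image[np.clip(yi, 0, n - 1), np.clip(xi, 0, n - 1)] * wx * wy, 0.0).sum(axis=1)
        out[v] = acc * step_px * pixel_spacing
    return out


class TestForwardProjection:
    def test_zero_image_gives_zero_sinogram(self, small_parallel_geometry):
        sino = forward_project_parallel(
            np.zeros((64, 64)), 1.0, small_parallel_geometry
        )
        assert np.all(sino.values == 0)

    def test_uniform_disk_chord_lengths(self, disk_sinogram, small_parallel_geometry):
        """The central detector of a centered disk reads 2 mu r at every
        angle; off-center detectors read the chord 2 mu sqrt(r^2 - t^2)
        up to pixelation error of the hard-edged fixture."""
        mu, r = 0.02, 40.0
        t = small_parallel_geometry.detector_offsets
        center = np.argmin(np.abs(t))
        np.testing.assert_allclose(
            disk_sinogram.values[:, center], 2 * mu * r, rtol=0.012
        )
        inside = np.abs(t) < r - 2
        expected = 2 * mu * np.sqrt(r**2 - t[inside] ** 2)
        sub = disk_sinogram.values[::7, inside]
        np.testing.assert_allclose(
            sub, np.broadcast_to(expected, sub.shape), rtol=0.05
        )

    def test_linearity(self, small_parallel_geometry, rng):
        img1 = rng.random((64, 64))
        img2 = rng.random((64, 64))
        p = lambda im: forward_project_parallel(im, 1.0, small_parallel_geometry).values
        np.testing.assert_allclose(
            p(2.0 * img1 + 0.5 * img2), 2.0 * p(img1) + 0.5 * p(img2), atol=1e-12
        )

    def test_mass_conservation_across_angles(self, disk_sinogram):
        """Total attenuation mass (sum x detector spacing) is angle-independent."""
        mass = disk_sinogram.values.sum(axis=1) * 1.0
        assert mass.std() / mass.mean() < 0.01

    def test_matches_ray_marching_oracle(self):
        """Joseph projector agrees with 0.1-pixel ray marching within 0.5%."""
        geom = ProjectionGeometry("parallel", 96, 1.0, 120)
        img = make_disk(n=80, radius_mm=25.0, mu=0.02, soft_edge=True)
        img[30:40, 45:60] += 0.015  # break symmetry
        fast = forward_project_parallel(img, 1.0, geom).values
        slow = ray_march_project(img, 1.0, geom)
        rel = np.linalg.norm(fast - slow) / np.linalg.norm(slow)
        assert rel < 0.005

    def test_rejects_non_square_image(self, small_parallel_geometry):
        with pytest.raises(ValueError, match="square"):
            forward_project_parallel(np.zeros((32, 48)), 1.0, small_parallel_geometry)

    def test_warns_on_negative_attenuation(self, small_parallel_geometry):
        with pytest.warns(UserWarning, match="negative"):
            forward_project_parallel(
                -np.ones((32, 32)), 1.0, small_parallel_geometry
            )


class TestGeometryInvariants:
    def test_nyquist_complete_flag(self):
        g = ProjectionGeometry("parallel", 728, 0.75, 1152)
        assert g.nyquist_complete  # 1152 >= pi/2 * 728 = 1143.5
        g2 = ProjectionGeometry("parallel", 728, 0.75, 1100)
        assert not g2.nyquist_complete

    def test_parallel_angles_span_half_rotation(self):
        g = ProjectionGeometry("parallel", 64, 1.0, 128)
        sino = forward_project_parallel(np.zeros((32, 32)), 1.0, g)
        assert sino.view_angles.size == 64
        assert sino.view_angles[0] == 0.0
        assert sino.view_angles[-1] < np.pi

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ProjectionGeometry("cone", 10, 1.0, 10)
        with pytest.raises(ValueError):
            ProjectionGeometry("fan", 10, 1.0, 10)  # missing source distances


def fan_disk_sinogram(geom, mu, radius):
    """Analytic fan-beam sinogram of a centered uniform disk."""
    gamma = geom.detector_offsets / geom.source_to_detector
    d = geom.source_to_isocenter * np.sin(gamma)  # ray distance to isocenter
    chord = 2 * mu * np.sqrt(np.clip(radius**2 - d**2, 0, None))
    angles = geom.start_angle + np.arange(geom.n_views_per_rotation) * (
        2 * np.pi / geom.n_views_per_rotation
    )
    return Sinogram(np.tile(chord, (angles.size, 1)), geom, angles)


class TestRebinning:
    fan_geom = ProjectionGeometry(
        "fan",
        256,
        1.2,
        512,
        source_to_detector=1085.6,
        source_to_isocenter=595.0,
    )
    par_geom = ProjectionGeometry("parallel", 128, 1.0, 512)

    def test_view_count_halves(self):
        fan = fan_disk_sinogram(self.fan_geom, 0.02, 40.0)
        par = rebin_fan_to_parallel(fan, self.par_geom)
        assert par.n_views == 256
        assert par.view_angles.size == self.fan_geom.n_views_per_rotation // 2

    def test_center_ray_identity(self):
        """The fan ray through the isocenter maps to parallel offset 0."""
        fan = fan_disk_sinogram(self.fan_geom, 0.02, 40.0)
        par = rebin_fan_to_parallel(fan, self.par_geom)
        t = self.par_geom.detector_offsets
        center = np.argmin(np.abs(t))
        # central chord of the disk = 2 mu r, up to interpolation
        np.testing.assert_allclose(par.values[:, center], 2 * 0.02 * 40.0, rtol=0.01)

    def test_disk_rebin_matches_direct_parallel(self):
        """Rebinned fan data of a disk equals its direct parallel projection."""
        mu, r = 0.02, 40.0
        fan = fan_disk_sinogram(self.fan_geom, mu, r)
        par = rebin_fan_to_parallel(fan, self.par_geom)
        t = self.par_geom.detector_offsets
        expected = 2 * mu * np.sqrt(np.clip(r**2 - t**2, 0, None))
        inside = np.abs(t) < r - 2
        err = np.linalg.norm(par.values[:, inside] - expected[inside][None, :])
        assert err / np.linalg.norm(expected[inside]) / np.sqrt(par.n_views) < 0.01

    def test_partial_rotation_rejected(self):
        geom = self.fan_geom
        fan = fan_disk_sinogram(geom, 0.02, 40.0)
        half = Sinogram(
            fan.values[:200], geom, fan.view_angles[:200]
        )
        with pytest.raises(ValueError, match="full rotation"):
            rebin_fan_to_parallel(half, self.par_geom)

    def test_parallel_input_rejected(self, disk_sinogram):
        with pytest.raises(ValueError, match="fan"):
            rebin_fan_to_parallel(disk_sinogram, self.par_geom)
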