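"""Radial k-space formation, Voronoi density compensation, gridding."""

import numpy as np
import pytest

from kwia.geometry import ProjectionGeometry, Sinogram, forward_project_parallel
from kwia.kspace import (
    KernelSpec,
    RadialKSpace,
    inverse_fft_and_deapodize,
    projections_to_radial_kspace,
    ramp_weights,
    regrid_to_cartesian,
    voronoi_weights,
)

from conftest import make_disk


class TestRadialKSpace:
    def test_constant_projection_is_dc_impulse(self):
        geom = ProjectionGeometry("parallel", 64, 1.0, 32)
        sino = Sinogram(np.ones((16, 64)), geom)
        ks = projections_to_radial_kspace(sino)
        dc = ks.samples[:, ks.dc_index]
        np.testing.assert_allclose(dc.real, 64.0, rtol=1e-12)
        off_dc = np.delete(ks.samples, ks.dc_index, axis=1)
        assert np.abs(off_dc).max() < 1e-9

    def test_dc_equals_total_mass_every_view(self, disk_sinogram):
        ks = projections_to_radial_kspace(disk_sinogram)
        dc = ks.samples[:, ks.dc_index].real
        mass = disk_sinogram.values.sum(axis=1) * 1.0
        np.testing.assert_allclose(dc, mass, rtol=1e-10)

    def test_conjugate_symmetry_for_real_projections(self, disk_sinogram):
        ks = projections_to_radial_kspace(disk_sinogram)
        m = ks.radial_indices
        for k in (1, 5, 20):
            a = ks.samples[:, ks.dc_index + k]
            b = ks.samples[:, ks.dc_index - k]
            np.testing.assert_allclose(a, np.conj(b), atol=1e-9 * np.abs(a).max())

    def test_central_slice_matches_2d_dft_axis_aligned(self):
        """The axis-aligned spoke equals the direct 2D DFT of the image."""
        n = 64
        img = make_disk(n=n, radius_mm=18.0, mu=1.0, soft_edge=True)
        geom = ProjectionGeometry("parallel", n, 1.0, 72)
        ks = projections_to_radial_kspace(forward_project_parallel(img, 1.0, geom))
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[:n, :n]
        for m in (-20, -7, 3, 11):
            direct = (img * np.exp(-2j * np.pi * m / n * (xx - c))).sum()
            sample = ks.samples[0, ks.dc_index + m]
            assert abs(sample - direct) / abs(direct) < 1e-9

    def test_disk_radial_profile_matches_analytic_jinc(self):
        """The view-averaged radial profile of a centered disk follows the
        analytic Airy-pattern (jinc) transform within 1%."""
        from scipy.special import j1

        n, r, mu = 64, 18.0, 1.0
        img = make_disk(n=n, radius_mm=r, mu=mu)
        geom = ProjectionGeometry("parallel", n, 1.0, 72)
        ks = projections_to_radial_kspace(forward_project_parallel(img, 1.0, geom))
        m = ks.radial_indices.astype(float)
        q = np.abs(m) / n  # cycles/mm at unit spacing
        with np.errstate(invalid="ignore", divide="ignore"):
            jinc = np.where(
                q == 0,
                mu * np.pi * r**2,
                mu * np.pi * r**2 * 2 * j1(2 * np.pi * q * r) / (2 * np.pi * q * r),
            )
        profile = ks.samples.mean(axis=0).real
        sel = np.abs(m) <= n // 4
        rel = np.linalg.norm(profile[sel] - jinc[sel]) / np.linalg.norm(jinc[sel])
        assert rel < 0.01

    def test_fan_input_rejected(self):
        geom = ProjectionGeometry(
            "fan", 32, 1.0, 64, source_to_detector=1000.0, source_to_isocenter=500.0
        )
        sino = Sinogram(np.zeros((64, 32)), geom, np.linspace(0, 2 * np.pi, 64, endpoint=False))
        with pytest.raises(ValueError, match="rebin"):
            projections_to_radial_kspace(sino)


class TestVoronoiWeights:
    def _kspace(self, n_views=48, n_det=64):
        angles = np.arange(n_views) * np.pi / n_views
        return RadialKSpace(np.zeros((n_views, n_det), complex), angles, n_det, 1.0)

    def test_interior_weights_follow_ramp(self):
        ks = self._kspace()
        w = voronoi_weights(ks, use_cache=False)
        m = np.abs(ks.radial_indices)
        interior = (m >= 2) & (m < 30)
        expected = m[interior] * np.pi / ks.n_views
        ratio = w[:, interior] / expected[None, :]
        assert np.abs(ratio - 1).max() < 0.02

    def test_total_weight_is_disk_area(self):
        ks = self._kspace()
        w = voronoi_weights(ks, use_cache=False)
        disk = np.pi * 32.0**2
        assert w.sum() == pytest.approx(disk, rel=0.01)

    def test_doubling_views_halves_interior_weights(self):
        w1 = voronoi_weights(self._kspace(n_views=40), use_cache=False)
        w2 = voronoi_weights(self._kspace(n_views=80), use_cache=False)
        m = np.abs(self._kspace().radial_indices)
        sel = (m >= 3) & (m < 28)
        ratio = w2[:, sel].mean() / w1[:, sel].mean()
        assert ratio == pytest.approx(0.5, rel=0.02)

    def test_dc_weight_shared_across_views(self):
        ks = self._kspace()
        w = voronoi_weights(ks, use_cache=False)
        dc_total = w[:, ks.dc_index].sum()
        # the DC cell is approximately a disk of radius 1/2
        assert dc_total == pytest.approx(np.pi * 0.25, rel=0.05)
        assert np.allclose(w[:, ks.dc_index], w[0, ks.dc_index])

    def test_ramp_weights_agree_with_voronoi(self):
        ks = self._kspace()
        wv = voronoi_weights(ks, use_cache=False)
        wr = ramp_weights(ks)
        m = np.abs(ks.radial_indices)
        sel = (m >= 2) & (m < 30)
        assert np.abs(wv[:, sel] / wr[:, sel] - 1).max() < 0.02


class TestGridding:
    def test_kernel_defaults(self):
        k = KernelSpec()
        assert (k.kb_beta, k.width, k.oversampling) == (16.25, 7, 2)

    def test_dc_impulse_grids_to_flat_image(self):
        """A single unit DC sample reconstructs to a flat image after
        deapodization (kernel self-consistency)."""
        n_det, n_views = 64, 48
        angles = np.arange(n_views) * np.pi / n_views
        samples = np.zeros((n_views, n_det), complex)
        ks = RadialKSpace(samples, angles, n_det, 1.0)
        samples[:, ks.dc_index] = 1.0
        w = np.zeros((n_views, n_det))
        w[:, ks.dc_index] = 1.0 / n_views  # shared DC sample
        kernel = KernelSpec()
        grid = regrid_to_cartesian(ks, w, kernel)
        img = inverse_fft_and_deapodize(grid, kernel, 48, n_det, 1.0)
        central = img[8:40, 8:40]
        assert (central.max() - central.min()) / np.abs(central).max() < 1e-3

    def test_pipeline_matches_brute_force_ndft(self):
        """Gridding reconstruction equals the direct nonuniform DFT within 1%."""
        n = 64
        img = make_disk(n=n, radius_mm=20.0, mu=0.02, soft_edge=True)
        geom = ProjectionGeometry("parallel", n, 1.0, 180)
        sino = forward_project_parallel(img, 1.0, geom)
        ks = projections_to_radial_kspace(sino)
        w = voronoi_weights(ks, use_cache=False)
        kernel = KernelSpec()
        grid = regrid_to_cartesian(ks, w, kernel)
        rec = inverse_fft_and_deapodize(grid, kernel, n, n, 1.0)

        # independent oracle: direct NDFT sum over all samples
        m = ks.radial_indices.astype(float)
        kx = (m[None, :] / n) * np.cos(ks.angles)[:, None]
        ky = (m[None, :] / n) * np.sin(ks.angles)[:, None]
        c = (n - 1) / 2.0
        coords = np.arange(n) - c
        f = (ks.samples * w).ravel()
        kxf, kyf = kx.ravel(), ky.ravel()
        oracle = np.zeros((n, n))
        for i, y in enumerate(coords):
            ph = np.exp(2j * np.pi * (np.outer(coords, kxf) + kyf[None, :] * y))
            oracle[i] = (ph * f[None, :]).sum(axis=1).real
        oracle /= (n * 1.0) ** 2  # d^2 nu = 1 / (D s)^2 per sample, D = n, s = 1
        rel = np.linalg.norm(rec - oracle) / np.linalg.norm(oracle)
        assert rel < 0.01

    def test_linearity_of_reconstruction(self, disk_sinogram):
        ks = projections_to_radial_kspace(disk_sinogram)
        w = voronoi_weights(ks)
        kernel = KernelSpec()
        g1 = regrid_to_cartesian(ks, w, kernel)
        ks3 = RadialKSpace(3.0 * ks.samples, ks.angles, ks.n_detectors, ks.detector_spacing)
        g3 = regrid_to_cartesian(ks3, w, kernel)
        r1 = inverse_fft_and_deapodize(g1, kernel, 64, ks.n_detectors, 1.0)
        r3 = inverse_fft_and_deapodize(g3, kernel, 64, ks.n_detectors, 1.0)
        np.testing.assert_allclose(r3, 3.0 * r1, rtol=1e-10, atol=1e-14)

    def test_kernel_wider_than_grid_rejected(self):
        ks = RadialKSpace(np.zeros((8, 4), complex), np.arange(8) * np.pi / 8, 4, 1.0)
        with pytest.raises(ValueError, match="width"):
            regrid_to_cartesian(ks, np.ones((8, 4)), KernelSpec(16.25, 11, 1))
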