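"""Projectors, FBP, resolution-coupling operators, WLS weights."""

import numpy as np
import pytest

from hybridct import geometry as G


def _disk(n, dx, radius):
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - n / 2 + 0.5, xx - n / 2 + 0.5) * dx
    return (r <= radius).astype(float), r


@pytest.fixture(scope="module")
def par_geom():
    return G.SystemGeometry(
        "parallel2d", n_views=96, n_det=40, det_pitch=0.5, vol_shape=(32, 32), voxel_size=0.5
    )


@pytest.fixture(scope="module")
def fan_geom():
    return G.SystemGeometry(
        "fan2d", n_views=120, n_det=44, det_pitch=0.6, vol_shape=(32, 32),
        voxel_size=0.5, sdd=270.0, sod=200.0,
    )


class TestMagnification:
    @pytest.mark.parametrize(
        "sdd,sod,expected", [(800, 700, 1.14), (270, 200, 1.35), (123.4, 123.4, 1.0)]
    )
    def test_values(self, sdd, sod, expected):
        assert G.magnification(sdd, sod) == pytest.approx(expected, abs=0.005)

    def test_invalid(self):
        with pytest.raises(ValueError):
            G.magnification(100, -1)
        with pytest.raises(ValueError):
            G.magnification(100, 200)


class TestProjectors:
    def test_zero_volume_zero_sinogram(self, par_geom):
        s = G.forward_project(G.Volume(np.zeros((32, 32)), 0.5), par_geom)
        assert np.all(s == 0)

    @pytest.mark.parametrize("geom_name", ["par_geom", "fan_geom"])
    def test_central_ray_equals_chord(self, geom_name, request):
        """Unit-attenuation disk: the central ray integral equals the
        diameter (analytic chord oracle)."""
        geom = request.getfixturevalue(geom_name)
        disk, _ = _disk(32, 0.5, 6.0)
        s = G.forward_project(G.Volume(disk, 0.5), geom)
        central = s[0, geom.n_det // 2 - 1 : geom.n_det // 2 + 1].max()
        assert central == pytest.approx(12.0, rel=0.01)

    def test_linearity(self, fan_geom, rng):
        x = rng.normal(size=(32, 32))
        y = rng.normal(size=(32, 32))
        pa = G.forward_project(G.Volume(2.0 * x + 3.0 * y, 0.5), fan_geom)
        pb = 2.0 * G.forward_project(G.Volume(x, 0.5), fan_geom) + 3.0 * G.forward_project(
            G.Volume(y, 0.5), fan_geom
        )
        assert np.allclose(pa, pb, atol=1e-10)

    @pytest.mark.parametrize("geom_name", ["par_geom", "fan_geom"])
    def test_adjointness(self, geom_name, request, rng):
        """<Px, y> = <x, P^T y> below 1e-3 relative (inner-product oracle)."""
        geom = request.getfixturevalue(geom_name)
        x = rng.normal(size=geom.vol_shape)
        y = rng.normal(size=geom.sino_shape)
        px = G.forward_project(G.Volume(x, geom.voxel_size), geom)
        pty = G.back_project(y, geom).data
        mismatch = abs(np.vdot(px, y) - np.vdot(x, pty))
        assert mismatch / (np.linalg.norm(px) * np.linalg.norm(y)) < 1e-3

    def test_adjointness_fan3d(self, rng):
        geom = G.SystemGeometry(
            "fan3d", n_views=36, n_det=28, det_pitch=0.6, vol_shape=(4, 20, 20),
            voxel_size=0.5, sdd=270.0, sod=200.0,
        )
        x = rng.normal(size=geom.vol_shape)
        y = rng.normal(size=geom.sino_shape)
        px = G.forward_project(G.Volume(x, geom.voxel_size), geom)
        pty = G.back_project(y, geom).data
        mismatch = abs(np.vdot(px, y) - np.vdot(x, pty))
        assert mismatch / (np.linalg.norm(px) * np.linalg.norm(y)) < 1e-3

    def test_back_projection_support(self, par_geom):
        s = np.zeros(par_geom.sino_shape)
        s[0, par_geom.n_det // 2] = 1.0
        vol = G.back_project(s, par_geom).data
        # at angle 0 the ray runs along y through the volume center
        nonzero_cols = np.unique(np.nonzero(vol)[1])
        assert len(nonzero_cols) <= 2
        assert np.all(np.abs(nonzero_cols - 15.5) < 2)

    def test_geometry_mismatch_rejected(self, par_geom):
        with pytest.raises(ValueError):
            G.forward_project(G.Volume(np.zeros((8, 8)), 0.5), par_geom)
        with pytest.raises(ValueError):
            G.back_project(np.zeros((3, 3)), par_geom)


class TestFBP:
    @pytest.mark.parametrize("mode", ["parallel2d", "fan2d"])
    def test_uniform_disk_value(self, mode):
        """Noise-free uniform cylinder reconstructs to its attenuation
        within 1% (simulator round trip at one energy)."""
        n, dx, mu = 96, 0.25, 0.02
        disk, r = _disk(n, dx, 8.0)
        if mode == "parallel2d":
            geom = G.SystemGeometry(mode, 180, 110, dx, (n, n), dx)
        else:
            geom = G.SystemGeometry(
                mode, 240, 120, dx * 1.35, (n, n), dx, sdd=270.0, sod=200.0
            )
        sino = G.forward_project(G.Volume(mu * disk, dx), geom)
        rec = G.fbp_reconstruct(sino, geom).data
        assert rec[r < 6.0].mean() == pytest.approx(mu, rel=0.01)

    def test_zero_sinogram(self):
        geom = G.SystemGeometry("parallel2d", 24, 16, 0.5, (12, 12), 0.5)
        assert np.all(G.fbp_reconstruct(np.zeros(geom.sino_shape), geom).data == 0)

    def test_point_psf_fwhm_about_two_voxels(self):
        """A point-like insert reconstructs with a PSF whose FWHM is
        about twice the voxel width at matched detector sampling."""
        n, dx = 128, 0.25
        vol = np.zeros((n, n))
        vol[n // 2, n // 2] = 1.0
        geom = G.SystemGeometry("parallel2d", 360, 150, dx, (n, n), dx)
        sino = G.forward_project(G.Volume(vol, dx), geom)
        rec = G.fbp_reconstruct(sino, geom).data
        prof = rec[n // 2]
        half = prof.max() / 2
        above = np.where(prof >= half)[0]
        fwhm_vox = above[-1] - above[0] + 1
        assert 1 <= fwhm_vox <= 3

    def test_insufficient_angular_range(self):
        geom = G.SystemGeometry(
            "parallel2d", 10, 16, 0.5, (12, 12), 0.5, angular_range=0.5
        )
        with pytest.raises(ValueError):
            G.fbp_reconstruct(np.zeros(geom.sino_shape), geom)


class TestResamplingSigma:
    def test_published_psf_pair(self):
        assert G.resampling_sigma(0.254, 0.176) == pytest.approx(0.078, abs=5e-4)

    def test_equal_psfs(self):
        assert G.resampling_sigma(0.3, 0.3) == 0.0

    def test_fwhm_sigma_identity(self):
        fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0))
        assert G.resampling_sigma(fwhm, 0.0) == pytest.approx(1.0, rel=1e-12)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            G.resampling_sigma(0.1, 0.2)


class TestResolutionCoupling:
    def test_constant_scales_by_c(self):
        vol = G.Volume(np.full((24, 24), 3.0), 0.088)
        out = G.blur_downsample(vol, 0.078, 0.127, c=1.443)
        inner = out.data[2:-2, 2:-2]
        assert np.allclose(inner, 3.0 * 1.443, rtol=1e-6)

    def test_identity_limit(self):
        vol = G.Volume(np.arange(64.0).reshape(8, 8), 0.1)
        out = G.blur_downsample(vol, 0.0, 0.1)
        assert np.allclose(out.data, vol.data)

    def test_gaussian_blob_widens_by_quadrature(self):
        """A Gaussian blob of sigma0 comes out with
        sqrt(sigma0^2 + sigma_r^2) (closed-form convolution)."""
        n, dx = 161, 0.1
        x = (np.arange(n) - n // 2) * dx
        sigma0, sigma_r = 0.5, 0.3
        blob = np.exp(-(x[None, :] ** 2 + x[:, None] ** 2) / (2 * sigma0**2))
        out = G.blur_downsample(G.Volume(blob, dx), sigma_r, dx).data
        prof = out[n // 2]
        sig_est = np.sqrt(np.sum(prof * x**2) / np.sum(prof))
        assert sig_est == pytest.approx(np.hypot(sigma0, sigma_r), rel=0.01)

    def test_transpose_constant_and_roundtrip(self):
        c = 1.443
        lo = G.Volume(np.full((16, 16), 2.0), 0.127)
        up = G.upsample_transpose(lo, 0.078, 0.088, c=c)
        assert np.allclose(up.data[4:-4, 4:-4], 2.0 / c, rtol=1e-6)
        hi = G.Volume(np.full((23, 23), 5.0), 0.088)
        down = G.blur_downsample(hi, 0.078, 0.127, c=c)
        back = G.upsample_transpose(down, 0.078, 0.088, c=c, out_shape=(23, 23))
        assert np.allclose(back.data[4:-4, 4:-4], 5.0, rtol=1e-6)

    def test_exact_adjoint_duality(self, rng):
        """<Bx, y> = <x, B^T y> to 1e-6 for the solver's adjoint pair on
        interior-supported volumes."""
        hi_shape, lo_shape = (33, 33), (23, 23)
        x = np.zeros(hi_shape)
        x[8:-8, 8:-8] = rng.normal(size=(17, 17))
        y = np.zeros(lo_shape)
        y[6:-6, 6:-6] = rng.normal(size=(11, 11))
        bx = G.blur_downsample(
            G.Volume(x, 0.088), 0.078, 0.127, out_shape=lo_shape
        ).data
        bty = G.blur_downsample_adjoint(
            G.Volume(y, 0.127), 0.078, 0.088, out_shape=hi_shape
        ).data
        lhs = np.vdot(bx, y)
        rhs = np.vdot(x, bty)
        assert abs(lhs - rhs) / max(abs(lhs), 1e-12) < 1e-6

    def test_upsampled_noise_is_correlated(self, rng):
        """White noise upsampled through B^T acquires spatial
        correlation on the scale of the resampling kernel."""
        lo = G.Volume(rng.normal(size=(64, 64)), 0.127)
        up = G.upsample_transpose(lo, 0.078, 0.088).data
        inner = up[4:-4, 4:-4]
        d = inner - inner.mean()
        corr1 = np.mean(d[:, 1:] * d[:, :-1]) / np.mean(d * d)
        assert corr1 > 0.3  # neighboring voxels strongly correlated

    def test_invalid_direction(self):
        with pytest.raises(ValueError):
            G.blur_downsample(G.Volume(np.zeros((8, 8)), 0.2), 0.1, 0.1)
        with pytest.raises(ValueError):
            G.upsample_transpose(G.Volume(np.zeros((8, 8)), 0.1), 0.1, 0.2)


class TestWlsWeights:
    def test_zero_line_integral(self):
        assert G.wls_weights(np.array([0.0]), g=2.5, eta=3.0)[0] == pytest.approx(2.5)

    def test_at_eta(self):
        assert G.wls_weights(np.array([3.0]), g=1.0, eta=3.0)[0] == pytest.approx(np.e)

    def test_monotone_in_attenuation(self, rng):
        w = np.sort(rng.uniform(0, 8, 32))
        q2 = G.wls_weights(w)
        assert np.all(np.diff(q2) >= 0)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            G.wls_weights(np.zeros(3), g=0.0)
        with pytest.raises(ValueError):
            G.wls_weights(np.zeros(3), eta=-1.0)
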