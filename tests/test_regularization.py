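"""Noise estimation, tiling, joint bilateral filtration, RSKR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridct import regularization as R


class TestMad:
    def test_constant_volume_zero(self):
        assert R.estimate_noise_mad(np.full((8, 8, 8), 3.0)) == 0.0

    def test_white_noise_unbiased(self, rng):
        """MAD recovers the white-noise sigma within 5% (Monte Carlo)."""
        ests = [
            R.estimate_noise_mad(np.random.default_rng(s).normal(0, 1, (48, 48, 48)))
            for s in range(3)
        ]
        assert np.mean(ests) == pytest.approx(1.0, abs=0.05)

    def test_smooth_ramp_invisible(self, rng):
        noise = rng.normal(0, 1, (48, 48, 48))
        ramp = np.linspace(0, 20, 48)[:, None, None] * np.ones((48, 48, 48))
        a = R.estimate_noise_mad(noise)
        b = R.estimate_noise_mad(noise + ramp)
        assert b == pytest.approx(a, rel=0.05)

    def test_degenerate_size_rejected(self):
        with pytest.raises(ValueError):
            R.estimate_noise_mad(np.ones((1, 8, 8)))

    def test_works_in_2d(self, rng):
        est = R.estimate_noise_mad(rng.normal(0, 2.0, (128, 128)))
        assert est == pytest.approx(2.0, rel=0.1)


class TestTiling:
    def test_stride_one_identity(self, rng):
        x = rng.normal(size=(7, 9))
        assert np.array_equal(R.tile(x, 1), x)

    def test_index_map_hand_example(self):
        # g = 9, s = 3: tiled index 1 draws from source index 3
        idx = R._tile_index(9, 3)
        assert idx[1] == 3
        assert list(idx) == [0, 3, 6, 1, 4, 7, 2, 5, 8]

    @given(
        st.tuples(
            st.integers(2, 12), st.integers(2, 12), st.integers(2, 12)
        ),
        st.integers(1, 4),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_roundtrip_bijection(self, shape, s):
        x = np.arange(np.prod(shape), dtype=float).reshape(shape)
        assert np.array_equal(R.detile(R.tile(x, s), s, shape), x)

    def test_tiling_raises_apparent_noise_of_correlated_field(self, rng):
        """Upsampled (correlated) noise measures a higher MAD after
        tiling — the premise of the tiled filtration pass."""
        from hybridct.geometry import Volume, upsample_transpose

        diffs = []
        for seed in range(3):
            lo = np.random.default_rng(seed).normal(size=(40, 40))
            hi = upsample_transpose(Volume(lo, 0.127), 0.078, 0.088).data
            diffs.append(
                R.estimate_noise_mad(R.tile(hi, 3)) - R.estimate_noise_mad(hi)
            )
        assert np.all(np.asarray(diffs) > 0)


class TestJointBilateralFilter:
    def test_constant_unchanged(self):
        stack = np.stack([np.full((10, 10, 10), 2.0), np.full((10, 10, 10), -1.0)])
        out = R.joint_bilateral_filter(stack, [1.0, 1.0], 1.0, radius=3)
        assert np.allclose(out, stack)

    def test_strict_range_kernel_is_identity(self, rng):
        x = rng.normal(size=(1, 16, 16))
        out = R.joint_bilateral_filter(x, [1.0], 1e-12, radius=3)
        assert np.allclose(out, x)

    def test_wide_range_kernel_is_spherical_mean(self, rng):
        from scipy import ndimage

        x = rng.normal(size=(1, 20, 20, 20))
        out = R.joint_bilateral_filter(x, [1.0], 1e9, radius=3)
        offs = R.sphere_offsets(3, 3)
        kern = np.zeros((7, 7, 7))
        kern[tuple((offs + 3).T)] = 1.0
        kern /= kern.sum()
        mean = ndimage.convolve(x[0], kern, mode="constant")
        inner = (slice(4, -4),) * 3
        assert np.allclose(out[0][inner], mean[inner], atol=1e-10)

    def test_channel_permutation_equivariance(self, rng):
        """Permuting channels permutes outputs identically (the joint
        range kernel is channel-symmetric for matching sigma and h)."""
        stack = rng.normal(size=(3, 12, 12))
        out = R.joint_bilateral_filter(stack, [1.0, 1.0, 1.0], 1.5, radius=2)
        perm = [2, 0, 1]
        out_p = R.joint_bilateral_filter(stack[perm], [1.0] * 3, 1.5, radius=2)
        assert np.allclose(out_p, out[perm])

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(Exception):
            R.joint_bilateral_filter(rng.normal(size=(2, 8, 8)), [1.0], [1.0, -2.0], 2)


class TestBtv:
    def test_constant_stack_zero(self):
        stack = np.stack([np.full((8, 8), 1.0)])
        assert R.btv_value(stack, [1.0], 1.0, radius=2) == 0.0

    def test_filtering_reduces_btv(self, rng):
        x = rng.normal(size=(2, 16, 16))
        sig = [1.0, 1.0]
        filt = R.joint_bilateral_filter(x, sig, 1.5, radius=2)
        assert R.btv_value(filt, sig, 1.5, 2) < R.btv_value(x, sig, 1.5, 2)

    def test_noise_exceeds_matched_edge(self, rng):
        edge = np.zeros((1, 24, 24))
        edge[:, :, 12:] = 1.0
        noise = rng.normal(0, edge.std(), (1, 24, 24))
        assert R.btv_value(noise, [1.0], 1.0, 2) > R.btv_value(edge, [1.0], 1.0, 2)


class TestPrioritizedSvd:
    def test_identical_columns_rank_one(self):
        col = np.arange(36.0).reshape(6, 6)
        fac = R.prioritized_svd(np.stack([col] * 4), np.ones(4))
        assert fac.e[1] < 1e-10 * fac.e[0]
        assert np.allclose(np.abs(fac.vt[0]), np.abs(fac.vt[0][0]))

    def test_reconstruction_identity(self, rng):
        cols = rng.normal(size=(5, 9, 9))
        fac = R.prioritized_svd(cols, np.ones(5))
        rec = (fac.u @ np.diag(fac.e) @ fac.vt).T.reshape(5, 9, 9)
        assert np.abs(rec - cols).max() < 1e-6 * np.abs(cols).max()

    def test_priority_rotates_leading_vector(self, rng):
        """Doubling one column's priority pulls the first singular
        vector toward it (dense SVD oracle)."""
        cols = rng.normal(size=(3, 64))
        p1 = np.ones(3)
        p2 = np.array([1.0, 1.0, 4.0])
        u1 = np.linalg.svd((cols.reshape(3, -1) * p1[:, None]).T, full_matrices=False)[0][:, 0]
        fac = R.prioritized_svd(cols.reshape(3, 8, 8), p2)
        u2 = fac.u[:, 0]
        target = cols[2] / np.linalg.norm(cols[2])
        assert abs(np.dot(u2, target)) > abs(np.dot(u1, target))

    def test_nonfinite_rejected(self):
        bad = np.full((2, 4, 4), np.nan)
        with pytest.raises(ValueError):
            R.prioritized_svd(bad, np.ones(2))


class TestRskr:
    def test_noise_free_identical_structure_passthrough(self):
        base = np.zeros((24, 24))
        base[6:18, 6:18] = 1.0
        stack = np.stack([base, 0.5 * base, 2.0 * base])
        out, info = R.rskr(stack, np.ones(3), R.RegularizerConfig(bf_radius=3))
        assert np.abs(out - stack).max() <= 0.01 * stack.max()

    def test_h_scaling_rule(self):
        """Singular values (4, 1) with gamma 0.5 and h0 1.5 give
        h = (1.5, 3.0)."""
        e = np.array([4.0, 1.0])
        h = 1.5 * (e[0] / e) ** 0.5
        assert h[0] == pytest.approx(1.5)
        assert h[1] == pytest.approx(3.0)
        rng = np.random.default_rng(0)
        a = np.outer([2.0, 1.0], rng.normal(size=144)).reshape(2, 12, 12)
        out, info = R.rskr(a, np.ones(2), R.RegularizerConfig(bf_radius=2))
        assert info["h"][0] == pytest.approx(1.5)
        assert np.all(np.diff(info["h"]) >= 0)

    def test_denoises_and_converges_within_six_iterations(self, rng):
        base = np.zeros((32, 32))
        base[8:24, 8:24] = 1.0
        clean = np.stack([base, 0.6 * base, 1.4 * base])
        noisy = clean + rng.normal(0, 0.15, clean.shape)
        out, info = R.rskr(noisy, np.ones(3), R.RegularizerConfig(bf_radius=3))
        assert info["iterations"] <= 6
        assert np.sqrt(((out - clean) ** 2).mean()) < 0.5 * np.sqrt(
            ((noisy - clean) ** 2).mean()
        )

    def test_reprojection_mode_runs_and_reduces_rank_proxy(self, rng):
        """The optional reprojection recomposition (off by default)
        yields a valid stack whose nuclear norm does not exceed the
        input's."""
        base = np.zeros((24, 24))
        base[6:18, 6:18] = 1.0
        noisy = np.stack([base, 0.7 * base]) + rng.normal(0, 0.2, (2, 24, 24))
        cfg = R.RegularizerConfig(bf_radius=3, use_reprojection=True)
        out, _ = R.rskr(noisy, np.ones(2), cfg)

        def nuc(c):
            return np.linalg.svd(c.reshape(2, -1).T, compute_uv=False).sum()

        assert np.all(np.isfinite(out))
        assert nuc(out) <= nuc(noisy) * (1 + 1e-9)

    def test_nuclear_norm_not_increased(self, rng):
        base = np.zeros((24, 24))
        base[6:18, 10:20] = 1.0
        noisy = np.stack([base, base, 0.5 * base]) + rng.normal(0, 0.2, (3, 24, 24))
        p = np.ones(3)
        out, _ = R.rskr(noisy, p, R.RegularizerConfig(bf_radius=3))

        def nuc(c):
            return np.linalg.svd(c.reshape(3, -1).T, compute_uv=False).sum()

        assert nuc(out) <= nuc(noisy) * (1 + 1e-9)
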