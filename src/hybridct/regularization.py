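"""Rank-sparse regularization: MAD, tiling, joint BF/BTV, and RSKR.

RSKR (rank-sparse kernel regression) enforces matching intensity
gradient-sparsity patterns and low spectral rank on a matrix of
co-registered volumes.  It filters the left singular vectors of a
prioritized (column-weighted) SVD with joint bilateral filtration
inside a small internal Bregman loop, scaling the per-vector
regularization strength by singular-value ratios so that weak singular
vectors are regressed toward the structure of strong ones.

Tiling is a bijective voxel remapping (stride ``s``) that turns
low-frequency correlated noise into high-frequency noise so a
fixed-radius bilateral filter can remove it; each bilateral pass here
averages a tiled and an untiled filtration of the same input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit, prange

__all__ = [
    "RegularizerConfig",
    "SVDFactors",
    "estimate_noise_mad",
    "tile",
    "detile",
    "sphere_offsets",
    "joint_bilateral_filter",
    "btv_value",
    "prioritized_svd",
    "rskr",
]

_SQRT2 = np.sqrt(2.0)


@dataclass
class RegularizerConfig:
    """User-facing regularization parameters (defaults per the method)."""

    h0: float = 1.5  # noise multiplier for joint BF
    gamma: float = 0.5  # singular-value ratio exponent
    stride: int = 3  # tiling stride
    bf_radius: int = 6  # spherical BF domain radius (voxels)
    inner_tol: float = 0.01  # residual-magnitude change tolerance
    inner_max_iter: int = 6
    omp_n0: int = 5  # max atoms per patch during regularization
    patch_radius: int = 4  # radial patch radius for the dictionary
    n_atoms: int = 1024
    ksvd_iterations: int = 25
    ksvd_n0: int = 48  # max atoms per patch during training
    n_train_patches: int = 500_000
    use_reprojection: bool = False  # optional rank-reduction variant

    def __post_init__(self):
        if self.stride < 1 or self.bf_radius < 1 or self.gamma < 0:
            raise ValueError("invalid regularizer configuration")


def estimate_noise_mad(vol: np.ndarray) -> float:
    """Gaussian noise sigma via the MAD of all-high-pass Haar coefficients.

    One level of the undecimated Haar transform with unit-norm filters
    is applied along every axis; the noise standard deviation is
    ``1.4826 * median(|HH...H|)``, which is unbiased for white Gaussian
    noise because the filters preserve the noise variance.
    """
    v = np.asarray(vol, dtype=float)
    if any(n < 2 for n in v.shape):
        raise ValueError("volume too small for a Haar level along every axis")
    for ax in range(v.ndim):
        v = (np.roll(v, -1, axis=ax) - v) / _SQRT2
    return 1.4826 * float(np.median(np.abs(v)))


def _tile_index(g: int, s: int) -> np.ndarray:
    """Source index m for each tiled index n along one axis of length g."""
    n = np.arange(g)
    return s * (n % (g // s)) + (n * s) // g


def _pad_to_multiple(vol: np.ndarray, s: int) -> np.ndarray:
    pads = [(0, (-n) % s) for n in vol.shape]
    if any(p[1] for p in pads):
        vol = np.pad(vol, pads, mode="edge")
    return vol


def tile(vol: np.ndarray, s: int) -> np.ndarray:
    """Bijective aliasing remap with stride ``s`` (edge-padded to fit)."""
    if s == 1:
        return np.asarray(vol).copy()
    v = _pad_to_multiple(np.asarray(vol), s)
    idx = [_tile_index(g, s) for g in v.shape]
    return v[np.ix_(*idx)]


def detile(vol: np.ndarray, s: int, orig_shape: tuple | None = None) -> np.ndarray:
    """Inverse of :func:`tile`; crops back to ``orig_shape`` if given."""
    if s == 1:
        out = np.asarray(vol).copy()
    else:
        v = np.asarray(vol)
        if any(g % s for g in v.shape):
            raise ValueError("detile expects dimensions padded to multiples of s")
        out = np.empty_like(v)
        idx = [_tile_index(g, s) for g in v.shape]
        out[np.ix_(*idx)] = v
    if orig_shape is not None:
        out = out[tuple(slice(0, n) for n in orig_shape)]
    return out


def sphere_offsets(radius: int, ndim: int = 3) -> np.ndarray:
    """Integer offsets with Euclidean norm <= radius (the BF domain)."""
    r = int(radius)
    axes = [np.arange(-r, r + 1)] * ndim
    grids = np.meshgrid(*axes, indexing="ij")
    d2 = sum(g * g for g in grids)
    sel = d2 <= r * r
    return np.stack([g[sel] for g in grids], axis=1).astype(np.int64)


@njit(cache=True, parallel=True, fastmath=True)
def _jbf_3d(stack, offsets, inv_h2, out):
    """Joint bilateral filtration of a channel stack (nc, nz, ny, nx).

    The range weight at each offset is jointly computed over all
    channels (delta resampling kernel), then every channel is averaged
    with those same weights over the spherical domain.
    """
    nc, nz, ny, nx = stack.shape
    n_off = offsets.shape[0]
    for z in prange(nz):
        acc = np.empty(nc)
        for y in range(ny):
            for x in range(nx):
                for c in range(nc):
                    acc[c] = 0.0
                wsum = 0.0
                for o in range(n_off):
                    zz = z - offsets[o, 0]
                    yy = y - offsets[o, 1]
                    xx = x - offsets[o, 2]
                    if zz < 0 or zz >= nz or yy < 0 or yy >= ny or xx < 0 or xx >= nx:
                        continue
                    d2 = 0.0
                    for c in range(nc):
                        diff = stack[c, zz, yy, xx] - stack[c, z, y, x]
                        d2 += diff * diff * inv_h2[c]
                    w = np.exp(-0.5 * d2)
                    wsum += w
                    for c in range(nc):
                        acc[c] += w * stack[c, zz, yy, xx]
                for c in range(nc):
                    out[c, z, y, x] = acc[c] / wsum


def _as_4d(stack: np.ndarray) -> tuple[np.ndarray, bool]:
    if stack.ndim == 3:  # (nc, ny, nx) single-slice
        return stack[:, None, :, :], True
    return stack, False


def joint_bilateral_filter(
    stack: np.ndarray,
    sigmas: np.ndarray,
    h: np.ndarray | float,
    radius: int = 6,
) -> np.ndarray:
    """Edge-preserving joint filtration of co-registered channels.

    All channels share the jointly computed Gaussian range weights;
    channel ``c`` contributes intensity differences scaled by
    ``1 / (h_c * sigma_c)``.  The spatial domain is the discrete sphere
    of the given radius (delta resampling kernel, so the zero offset
    carries weight one).
    """
    stack = np.asarray(stack, dtype=np.float64)
    s4, squeeze = _as_4d(stack)
    nc = s4.shape[0]
    sigmas = np.broadcast_to(np.asarray(sigmas, dtype=float), (nc,))
    h = np.broadcast_to(np.asarray(h, dtype=float), (nc,))
    hs = h * sigmas
    if np.any(hs < 0):
        raise ValueError("h * sigma must be nonnegative")
    # channels with zero h*sigma would have an infinitely strict range
    # kernel; cap the inverse bandwidth so exactly-equal neighbors (and
    # only those) still average (0 * cap = 0)
    inv_h2 = np.minimum(1.0 / np.clip(hs, 1e-15, None) ** 2, 1e30)
    ndim = 2 if squeeze else 3
    offs = sphere_offsets(radius, ndim)
    if squeeze:
        offs = np.concatenate([np.zeros((offs.shape[0], 1), np.int64), offs], axis=1)
    out = np.empty_like(s4)
    _jbf_3d(s4, offs, inv_h2, out)
    return out[:, 0] if squeeze else out


def btv_value(
    stack: np.ndarray,
    sigmas: np.ndarray,
    h: np.ndarray | float,
    radius: int = 6,
) -> float:
    """Bilateral total variation: BF-weighted L1 norm of the gradients.

    Monitoring quantity only; joint BF is its minimization step.
    """
    stack = np.asarray(stack, dtype=np.float64)
    filtered = joint_bilateral_filter(stack, sigmas, h, radius)
    # the BF-weighted mean of Delta-K gradients equals filtered - input
    return float(np.sum(np.abs(filtered - stack)))


@dataclass
class SVDFactors:
    """Reduced SVD of the prioritized channel matrix."""

    u: np.ndarray  # (n_vox, n_u) left singular vectors
    e: np.ndarray  # (n_u,) singular values, descending
    vt: np.ndarray  # (n_u, n_cols)
    shape: tuple  # spatial shape of one channel
    priority: np.ndarray  # diagonal of P

    def volumes(self) -> np.ndarray:
        """Left singular vectors as a channel stack."""
        return self.u.T.reshape(-1, *self.shape)


def prioritized_svd(columns: np.ndarray, priority: np.ndarray) -> SVDFactors:
    """Weighted reduced SVD of a stack of volumes.

    ``columns`` is (n_cols, *spatial); column ``i`` is scaled by
    ``priority[i]`` before decomposition so high-fidelity channels
    dominate the leading singular vectors.
    """
    cols = np.asarray(columns, dtype=np.float64)
    if not np.all(np.isfinite(cols)):
        raise ValueError("non-finite input to prioritized SVD")
    p = np.asarray(priority, dtype=float)
    if p.ndim != 1 or p.size != cols.shape[0] or np.any(p <= 0):
        raise ValueError("priority must be a positive diagonal, one per column")
    shape = cols.shape[1:]
    a = (cols.reshape(cols.shape[0], -1) * p[:, None]).T  # (n_vox, n_cols)
    u, e, vt = np.linalg.svd(a, full_matrices=False)
    return SVDFactors(u=u, e=e, vt=vt, shape=shape, priority=p)


def _bf_average_pass(
    stack: np.ndarray, h: np.ndarray, cfg: RegularizerConfig
) -> np.ndarray:
    """One jBF pass: arithmetic mean of untiled and tiled filtration.

    Noise levels are re-measured by MAD immediately before each
    filtration, separately for the untiled and tiled views (tiling
    raises the apparent noise level of correlated noise, which is
    exactly what makes the tiled pass more aggressive).
    """
    sig_u = np.array([max(estimate_noise_mad(c), 1e-300) for c in stack])
    out_u = joint_bilateral_filter(stack, sig_u, h, cfg.bf_radius)

    orig_shape = stack.shape[1:]
    tiled = np.stack([tile(c, cfg.stride) for c in stack])
    sig_t = np.array([max(estimate_noise_mad(c), 1e-300) for c in tiled])
    out_t = joint_bilateral_filter(tiled, sig_t, h, cfg.bf_radius)
    out_t = np.stack([detile(c, cfg.stride, orig_shape) for c in out_t])
    return 0.5 * (out_u + out_t)


def rskr(
    columns: np.ndarray,
    priority: np.ndarray,
    cfg: RegularizerConfig,
) -> tuple[np.ndarray, dict]:
    """Rank-sparse kernel regression of a stack of co-registered volumes.

    Decomposes the prioritized column matrix, filters the singular
    vectors under a BTV constraint with an internal Bregman loop
    (add-residual-back), recomposes with the original singular values,
    and removes the priority weighting.  Returns the regularized stack
    and a diagnostics dict (iterations, residual history, h_i).
    """
    cols = np.asarray(columns, dtype=np.float64)
    fac = prioritized_svd(cols, priority)
    keep = fac.e > fac.e[0] * 1e-12
    n_u = int(keep.sum())
    u0 = fac.volumes()[:n_u]
    h = cfg.h0 * (fac.e[0] / fac.e[:n_u]) ** cfg.gamma

    u = u0.copy()
    f = np.zeros_like(u)
    hb = h.reshape(-1, *([1] * (u.ndim - 1)))
    res_hist = []
    prev_mag = None
    n_iter = 0
    for it in range(cfg.inner_max_iter):
        n_iter = it + 1
        l = _bf_average_pass(u + f, h, cfg)
        f = f + u - l
        u = (u0 + hb * (l - f)) / (1.0 + hb)
        mag = float(np.linalg.norm(f))
        res_hist.append(mag)
        if prev_mag is not None and abs(mag - prev_mag) <= cfg.inner_tol * max(
            prev_mag, 1e-300
        ):
            break
        prev_mag = mag
    u_flat = u.reshape(n_u, -1).T
    if cfg.use_reprojection:
        a = (cols.reshape(cols.shape[0], -1) * fac.priority[:, None]).T
        d = u_flat @ (u_flat.T @ a)
    else:
        d = u_flat @ (np.diag(fac.e[:n_u]) @ fac.vt[:n_u])
    # pass through any dropped null vectors unchanged (they carry no data)
    out = (d.T / fac.priority[:, None]).reshape(cols.shape)
    info = {"iterations": n_iter, "residual_history": res_hist, "h": h}
    return out, info
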