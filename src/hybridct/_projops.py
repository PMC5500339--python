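"""Numba ray-tracing kernels for the tomographic operators.

The forward projector is a Joseph-style interpolating ray tracer that
steps along the dominant axis of each ray and accumulates linearly
interpolated samples; the algebraic backprojector scatters exactly the
same weights, so the pair is an exact matrix transpose.  A separate
pixel-driven backprojector is used for filtered backprojection.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange


@njit(cache=True, fastmath=True)
def _trace_forward(vol, sx, sy, ex, ey, delta):
    """Line integral through a 2D grid (mm^-1 * mm) for one ray."""
    ny, nx = vol.shape
    dx = ex - sx
    dy = ey - sy
    length = np.sqrt(dx * dx + dy * dy)
    if length == 0.0:
        return 0.0
    acc = 0.0
    if abs(dx) >= abs(dy):
        # march across x planes
        step = delta * length / abs(dx)
        for j in range(nx):
            x = (j + 0.5 - nx / 2.0) * delta
            t = (x - sx) / dx
            if t < 0.0 or t > 1.0:
                continue
            y = sy + t * dy
            fy = y / delta + ny / 2.0 - 0.5
            i0 = int(np.floor(fy))
            w1 = fy - i0
            if i0 >= 0 and i0 < ny:
                acc += (1.0 - w1) * vol[i0, j] * step
            if i0 + 1 >= 0 and i0 + 1 < ny:
                acc += w1 * vol[i0 + 1, j] * step
    else:
        step = delta * length / abs(dy)
        for i in range(ny):
            y = (i + 0.5 - ny / 2.0) * delta
            t = (y - sy) / dy
            if t < 0.0 or t > 1.0:
                continue
            x = sx + t * dx
            fx = x / delta + nx / 2.0 - 0.5
            j0 = int(np.floor(fx))
            w1 = fx - j0
            if j0 >= 0 and j0 < nx:
                acc += (1.0 - w1) * vol[i, j0] * step
            if j0 + 1 >= 0 and j0 + 1 < nx:
                acc += w1 * vol[i, j0 + 1] * step
    return acc


@njit(cache=True, fastmath=True)
def _trace_back(vol, val, sx, sy, ex, ey, delta):
    """Scatter ``val`` along one ray with the transposed Joseph weights."""
    ny, nx = vol.shape
    dx = ex - sx
    dy = ey - sy
    length = np.sqrt(dx * dx + dy * dy)
    if length == 0.0:
        return
    if abs(dx) >= abs(dy):
        step = delta * length / abs(dx)
        for j in range(nx):
            x = (j + 0.5 - nx / 2.0) * delta
            t = (x - sx) / dx
            if t < 0.0 or t > 1.0:
                continue
            y = sy + t * dy
            fy = y / delta + ny / 2.0 - 0.5
            i0 = int(np.floor(fy))
            w1 = fy - i0
            if i0 >= 0 and i0 < ny:
                vol[i0, j] += (1.0 - w1) * val * step
            if i0 + 1 >= 0 and i0 + 1 < ny:
                vol[i0 + 1, j] += w1 * val * step
    else:
        step = delta * length / abs(dy)
        for i in range(ny):
            y = (i + 0.5 - ny / 2.0) * delta
            t = (y - sy) / dy
            if t < 0.0 or t > 1.0:
                continue
            x = sx + t * dx
            fx = x / delta + nx / 2.0 - 0.5
            j0 = int(np.floor(fx))
            w1 = fx - j0
            if j0 >= 0 and j0 < nx:
                vol[i, j0] += (1.0 - w1) * val * step
            if j0 + 1 >= 0 and j0 + 1 < nx:
                vol[i, j0 + 1] += w1 * val * step


@njit(cache=True, parallel=True, fastmath=True)
def forward_2d(vol, rays, delta, out):
    """rays: (n, 4) array of [sx, sy, ex, ey]; out: (n,)."""
    for r in prange(rays.shape[0]):
        out[r] = _trace_forward(vol, rays[r, 0], rays[r, 1], rays[r, 2], rays[r, 3], delta)


@njit(cache=True, fastmath=True)
def back_2d(sino, rays, delta, vol):
    for r in range(rays.shape[0]):
        _trace_back(vol, sino[r], rays[r, 0], rays[r, 1], rays[r, 2], rays[r, 3], delta)


@njit(cache=True, parallel=True, fastmath=True)
def forward_3d(vol, rays, delta, out):
    """Slice-stacked fan geometry: vol (nz, ny, nx), out (nz, n_rays)."""
    nz = vol.shape[0]
    for z in prange(nz):
        for r in range(rays.shape[0]):
            out[z, r] = _trace_forward(
                vol[z], rays[r, 0], rays[r, 1], rays[r, 2], rays[r, 3], delta
            )


@njit(cache=True, parallel=True, fastmath=True)
def back_3d(sino, rays, delta, vol):
    nz = vol.shape[0]
    for z in prange(nz):
        for r in range(rays.shape[0]):
            _trace_back(
                vol[z], sino[z, r], rays[r, 0], rays[r, 1], rays[r, 2], rays[r, 3], delta
            )


@njit(cache=True, parallel=True, fastmath=True)
def fbp_back_parallel(filtered, angles, du, n_det, delta, vol):
    """Pixel-driven parallel-beam backprojection of filtered data."""
    ny, nx = vol.shape
    n_views = angles.shape[0]
    for i in prange(ny):
        y = (i + 0.5 - ny / 2.0) * delta
        for j in range(nx):
            x = (j + 0.5 - nx / 2.0) * delta
            acc = 0.0
            for k in range(n_views):
                th = angles[k]
                u = x * np.cos(th) + y * np.sin(th)
                fu = u / du + n_det / 2.0 - 0.5
                k0 = int(np.floor(fu))
                w1 = fu - k0
                if k0 >= 0 and k0 < n_det - 1:
                    acc += (1.0 - w1) * filtered[k, k0] + w1 * filtered[k, k0 + 1]
                elif k0 == n_det - 1 and w1 == 0.0:
                    acc += filtered[k, k0]
            vol[i, j] = acc


@njit(cache=True, parallel=True, fastmath=True)
def fbp_back_fan(filtered, angles, du_iso, n_det, delta, sod, vol):
    """Pixel-driven fan-beam backprojection with 1/U^2 weighting.

    ``filtered`` is sampled on the virtual detector through the
    isocenter (pitch ``du_iso``).
    """
    ny, nx = vol.shape
    n_views = angles.shape[0]
    for i in prange(ny):
        y = (i + 0.5 - ny / 2.0) * delta
        for j in range(nx):
            x = (j + 0.5 - nx / 2.0) * delta
            acc = 0.0
            for k in range(n_views):
                beta = angles[k]
                dhx = -np.sin(beta)
                dhy = np.cos(beta)
                sx = -sod * dhx
                sy = -sod * dhy
                rx = x - sx
                ry = y - sy
                t_par = rx * dhx + ry * dhy
                if t_par <= 0.0:
                    continue
                uprime = sod * (rx * dhy - ry * dhx) / t_par
                bigu = t_par / sod
                fu = uprime / du_iso + n_det / 2.0 - 0.5
                k0 = int(np.floor(fu))
                w1 = fu - k0
                if k0 >= 0 and k0 < n_det - 1:
                    val = (1.0 - w1) * filtered[k, k0] + w1 * filtered[k, k0 + 1]
                    acc += val / (bigu * bigu)
            vol[i, j] = acc
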