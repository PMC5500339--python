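"""System geometry, projection operators, FBP, and resolution coupling.

Geometry modes
--------------
``parallel2d``
    Parallel rays in a single slice; detector pitch is measured at the
    isocenter.
``fan2d``
    Flat-detector fan beam in a single slice (pitch at the physical
    detector, magnification sdd/sod).
``fan3d``
    A stack of identical fan-beam slices (circular scan with zero cone
    angle).  This is the desk-scale stand-in for a full cone-beam
    geometry: each reconstruction slice maps to one detector row.

All operators work in physical units: volumes are linear attenuation in
mm^-1, sinograms are unitless log line integrals (mm^-1 * mm).  The
forward/back projection pair is an exact matrix transpose by
construction (shared Joseph weights).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from . import _projops

__all__ = [
    "SystemGeometry",
    "Volume",
    "magnification",
    "forward_project",
    "back_project",
    "fbp_reconstruct",
    "resampling_sigma",
    "blur_downsample",
    "upsample_transpose",
    "blur_downsample_adjoint",
    "wls_weights",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class Volume:
    """Attenuation volume (mm^-1) with its voxel size (mm).

    ``data`` is (ny, nx) in the 2D modes and (nz, ny, nx) in ``fan3d``;
    voxel centers sit at ``(i + 0.5) * voxel - extent / 2`` so rotation
    is about the volume center.
    """

    data: np.ndarray
    voxel_size: float

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        self.data = np.asarray(self.data, dtype=np.float64)


def magnification(sdd_mm: float, sod_mm: float) -> float:
    """Geometric magnification sdd/sod of a divergent-beam chain."""
    if sod_mm <= 0 or sdd_mm <= 0:
        raise ValueError("distances must be positive")
    if sod_mm > sdd_mm:
        raise ValueError("source-object distance exceeds source-detector distance")
    return sdd_mm / sod_mm


@dataclass
class SystemGeometry:
    """Acquisition geometry for one imaging chain."""

    mode: str  # parallel2d | fan2d | fan3d
    n_views: int
    n_det: int
    det_pitch: float  # mm at the detector (at isocenter for parallel2d)
    vol_shape: tuple  # (ny, nx) or (nz, ny, nx)
    voxel_size: float  # mm
    sdd: float | None = None
    sod: float | None = None
    angular_range: float = 2.0 * np.pi
    chain: str = ""

    def __post_init__(self):
        if self.mode not in ("parallel2d", "fan2d", "fan3d"):
            raise ValueError(f"unknown geometry mode {self.mode!r}")
        if self.mode != "parallel2d":
            if self.sdd is None or self.sod is None:
                raise ValueError("divergent modes need sdd and sod")
            magnification(self.sdd, self.sod)  # validates
        if self.mode == "fan3d" and len(self.vol_shape) != 3:
            raise ValueError("fan3d expects a 3D volume shape")
        if self.mode != "fan3d" and len(self.vol_shape) != 2:
            raise ValueError("2D modes expect a 2D volume shape")

    @property
    def mag(self) -> float:
        return 1.0 if self.mode == "parallel2d" else magnification(self.sdd, self.sod)

    @property
    def du_iso(self) -> float:
        """Detector pitch referred to the isocenter plane."""
        return self.det_pitch / self.mag

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_views) * (self.angular_range / self.n_views)

    @property
    def sino_shape(self) -> tuple:
        if self.mode == "fan3d":
            return (self.vol_shape[0], self.n_views, self.n_det)
        return (self.n_views, self.n_det)

    def rays(self, det_offset: float = 0.0) -> np.ndarray:
        """Per-ray endpoints [sx, sy, ex, ey] (mm), view-major order.

        ``det_offset`` shifts every detector sample by that fraction of
        a cell (used to sub-sample the cell aperture in simulation).
        """
        u = (np.arange(self.n_det) + 0.5 + det_offset - self.n_det / 2.0) * self.det_pitch
        out = np.empty((self.n_views * self.n_det, 4))
        half_diag = 0.75 * max(self.vol_shape[-1], self.vol_shape[-2]) * self.voxel_size
        for k, ang in enumerate(self.angles):
            dhat = np.array([-np.sin(ang), np.cos(ang)])
            uhat = np.array([np.cos(ang), np.sin(ang)])
            sl = slice(k * self.n_det, (k + 1) * self.n_det)
            if self.mode == "parallel2d":
                p0 = u[:, None] * uhat[None, :]
                out[sl, 0:2] = p0 - half_diag * dhat[None, :]
                out[sl, 2:4] = p0 + half_diag * dhat[None, :]
            else:
                src = -self.sod * dhat
                det_c = src + self.sdd * dhat
                out[sl, 0] = src[0]
                out[sl, 1] = src[1]
                out[sl, 2] = det_c[0] + u * uhat[0]
                out[sl, 3] = det_c[1] + u * uhat[1]
        return out

    def with_slices(self, nz: int) -> "SystemGeometry":
        """Promote a 2D geometry to a slice-stacked 3D one."""
        if self.mode == "parallel2d":
            raise ValueError("only fan geometries stack into fan3d")
        return replace(self, mode="fan3d", vol_shape=(nz, *self.vol_shape[-2:]))


def _check(vol: Volume, geom: SystemGeometry):
    if tuple(vol.data.shape) != tuple(geom.vol_shape):
        raise ValueError(f"volume shape {vol.data.shape} != geometry {geom.vol_shape}")
    if abs(vol.voxel_size - geom.voxel_size) > 1e-9:
        raise ValueError("voxel size mismatch between volume and geometry")


def forward_project(
    vol: Volume, geom: SystemGeometry, det_offset: float = 0.0
) -> np.ndarray:
    """Ray-driven line integrals (mm^-1 * mm); linear in the volume."""
    _check(vol, geom)
    rays = geom.rays(det_offset)
    if geom.mode == "fan3d":
        out = np.empty((vol.data.shape[0], rays.shape[0]))
        _projops.forward_3d(vol.data, rays, geom.voxel_size, out)
        return out.reshape(geom.sino_shape)
    out = np.empty(rays.shape[0])
    _projops.forward_2d(vol.data, rays, geom.voxel_size, out)
    return out.reshape(geom.sino_shape)


def back_project(sino: np.ndarray, geom: SystemGeometry) -> Volume:
    """Exact transpose of :func:`forward_project`."""
    sino = np.asarray(sino, dtype=np.float64)
    if tuple(sino.shape) != geom.sino_shape:
        raise ValueError(f"sinogram shape {sino.shape} != geometry {geom.sino_shape}")
    rays = geom.rays()
    vol = np.zeros(geom.vol_shape)
    if geom.mode == "fan3d":
        _projops.back_3d(sino.reshape(sino.shape[0], -1), rays, geom.voxel_size, vol)
    else:
        _projops.back_2d(sino.ravel(), rays, geom.voxel_size, vol)
    return Volume(vol, geom.voxel_size)


def _ramp_kernel(n_det: int, du: float, apodization: str) -> np.ndarray:
    """Frequency response of the discrete Ram-Lak kernel (padded)."""
    n_pad = 1 << int(np.ceil(np.log2(4 * n_det)))
    n = np.arange(-n_det, n_det)
    h = np.zeros_like(n, dtype=float)
    h[n == 0] = 1.0 / (4.0 * du * du)
    odd = n % 2 == 1
    h[odd] = -1.0 / (np.pi * n[odd] * du) ** 2
    kern = np.zeros(n_pad)
    kern[: 2 * n_det] = h
    resp = np.real(np.fft.fft(np.roll(kern, -n_det)))
    if apodization == "hann":
        f = np.fft.fftfreq(n_pad)
        resp = resp * (0.5 * (1.0 + np.cos(2.0 * np.pi * f)))
    elif apodization != "ramp":
        raise ValueError("apodization must be 'ramp' or 'hann'")
    return resp


def _filter_rows(sino: np.ndarray, du: float, apodization: str) -> np.ndarray:
    n_views, n_det = sino.shape
    resp = _ramp_kernel(n_det, du, apodization)
    n_pad = resp.size
    spec = np.fft.fft(sino, n=n_pad, axis=1) * resp[None, :]
    return np.real(np.fft.ifft(spec, axis=1))[:, :n_det] * du


def _fbp_slice(sino: np.ndarray, geom: SystemGeometry, apodization: str) -> np.ndarray:
    angles = geom.angles
    full_turns = geom.angular_range / np.pi  # 2.0 for a full scan
    if full_turns < 1.0 - 1e-6:
        raise ValueError("FBP requires at least a half turn of angular coverage")
    vol = np.zeros(geom.vol_shape[-2:])
    if geom.mode == "parallel2d":
        filt = _filter_rows(sino, geom.du_iso, apodization)
        _projops.fbp_back_parallel(
            filt, angles, geom.du_iso, geom.n_det, geom.voxel_size, vol
        )
        vol *= (geom.angular_range / geom.n_views) / full_turns
    else:
        du = geom.du_iso
        u = (np.arange(geom.n_det) + 0.5 - geom.n_det / 2.0) * du
        weighted = sino * (geom.sod / np.sqrt(geom.sod**2 + u**2))[None, :]
        filt = _filter_rows(weighted, du, apodization)
        _projops.fbp_back_fan(
            filt, angles, du, geom.n_det, geom.voxel_size, geom.sod, vol
        )
        vol *= (geom.angular_range / geom.n_views) / full_turns
    return vol


def fbp_reconstruct(
    sino: np.ndarray, geom: SystemGeometry, apodization: str = "ramp"
) -> Volume:
    """Filtered backprojection (ramp by default, optional Hann)."""
    sino = np.asarray(sino, dtype=np.float64)
    if tuple(sino.shape) != geom.sino_shape:
        raise ValueError("sinogram does not match geometry")
    if geom.mode == "fan3d":
        out = np.empty(geom.vol_shape)
        geo2d = replace(geom, mode="fan2d", vol_shape=geom.vol_shape[-2:])
        for z in range(geom.vol_shape[0]):
            out[z] = _fbp_slice(sino[z], geo2d, apodization)
        return Volume(out, geom.voxel_size)
    return Volume(_fbp_slice(sino, geom, apodization), geom.voxel_size)


def resampling_sigma(fwhm_pcd_mm: float, fwhm_eid_mm: float) -> float:
    """Gaussian sigma coupling the two chain resolutions (mm).

    sigma_r = sqrt(FWHM_PCD^2 - FWHM_EID^2) / (2 sqrt(2 ln 2)).
    """
    if fwhm_eid_mm < 0 or fwhm_pcd_mm < fwhm_eid_mm:
        raise ValueError("need fwhm_pcd >= fwhm_eid >= 0")
    return float(np.sqrt(fwhm_pcd_mm**2 - fwhm_eid_mm**2) / _FWHM_TO_SIGMA)


def _resample_coords(n_out: int, out_voxel: float, n_in: int, in_voxel: float):
    """Voxel-center positions of the output grid in input index units."""
    centers = (np.arange(n_out) + 0.5 - n_out / 2.0) * out_voxel
    return centers / in_voxel + n_in / 2.0 - 0.5


def _out_shape(shape, in_voxel, out_voxel):
    return tuple(max(1, int(round(n * in_voxel / out_voxel))) for n in shape)


def blur_downsample(
    vol: Volume,
    sigma_mm: float,
    out_voxel: float,
    c: float = 1.0,
    out_shape: tuple | None = None,
) -> Volume:
    """The B operator: normalized Gaussian blur sampled on a coarser grid.

    A constant volume maps to ``c`` times the constant (``c = 1`` keeps
    attenuation values physical; the voxel-length-ratio scaling used
    with per-voxel units can be requested explicitly).
    """
    if out_voxel < vol.voxel_size - 1e-12:
        raise ValueError("output voxel must be at least as large as input voxel")
    if sigma_mm <= 0 and abs(out_voxel - vol.voxel_size) > 1e-12:
        raise ValueError("resampling without blur requires equal voxel sizes")
    data = vol.data
    if sigma_mm > 0:
        data = ndimage.gaussian_filter(data, sigma_mm / vol.voxel_size, mode="nearest")
    if abs(out_voxel - vol.voxel_size) <= 1e-12 and out_shape is None:
        return Volume(c * data, out_voxel)
    shape = out_shape or _out_shape(data.shape, vol.voxel_size, out_voxel)
    grids = np.meshgrid(
        *[
            _resample_coords(no, out_voxel, ni, vol.voxel_size)
            for no, ni in zip(shape, data.shape)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        data, np.stack([g.ravel() for g in grids]), order=1, mode="nearest"
    ).reshape(shape)
    return Volume(c * out, out_voxel)


def upsample_transpose(
    vol: Volume,
    sigma_mm: float,
    out_voxel: float,
    c: float = 1.0,
    out_shape: tuple | None = None,
) -> Volume:
    """The B^T operator: normalized-kernel interpolation to a finer grid.

    This is the value-preserving "logical transpose" used to upsample
    coarse reconstructions (a constant maps to constant / c); it is not
    the exact matrix adjoint of :func:`blur_downsample` — see
    :func:`blur_downsample_adjoint` for that.
    """
    if out_voxel > vol.voxel_size + 1e-12:
        raise ValueError("output voxel must be at most the input voxel")
    shape = out_shape or _out_shape(vol.data.shape, vol.voxel_size, out_voxel)
    if abs(out_voxel - vol.voxel_size) <= 1e-12 and tuple(shape) == vol.data.shape:
        out = vol.data
    else:
        grids = np.meshgrid(
            *[
                _resample_coords(no, out_voxel, ni, vol.voxel_size)
                for no, ni in zip(shape, vol.data.shape)
            ],
            indexing="ij",
        )
        out = ndimage.map_coordinates(
            vol.data, np.stack([g.ravel() for g in grids]), order=1, mode="nearest"
        ).reshape(shape)
    if sigma_mm > 0:
        out = ndimage.gaussian_filter(out, sigma_mm / out_voxel, mode="nearest")
    return Volume(out / c, out_voxel)


def blur_downsample_adjoint(
    vol: Volume,
    sigma_mm: float,
    out_voxel: float,
    c: float = 1.0,
    out_shape: tuple | None = None,
) -> Volume:
    """Exact matrix adjoint of :func:`blur_downsample`.

    Used inside the iterative solver so the coupled normal equations
    are the true gradient of the weighted least-squares objective.
    Implemented by transposing each stage of B: linear-interpolation
    scatter back to the fine grid, then the (self-adjoint) Gaussian.
    """
    if out_voxel > vol.voxel_size + 1e-12:
        raise ValueError("adjoint maps the coarse grid back to the fine grid")
    shape = out_shape or _out_shape(vol.data.shape, vol.voxel_size, out_voxel)
    out = np.zeros(shape)
    if abs(out_voxel - vol.voxel_size) <= 1e-12 and tuple(shape) == vol.data.shape:
        out[...] = vol.data
    else:
        # scatter with the transposed bilinear weights, axis by axis
        data = vol.data
        for ax, (n_in, n_out) in enumerate(zip(vol.data.shape, shape)):
            coords = _resample_coords(n_in, vol.voxel_size, n_out, out_voxel)
            w = np.zeros((n_in, n_out))
            lo = np.floor(coords).astype(int)
            frac = coords - lo
            for k in range(n_in):
                l0 = min(max(lo[k], 0), n_out - 1)
                l1 = min(max(lo[k] + 1, 0), n_out - 1)
                w[k, l0] += 1.0 - frac[k]
                w[k, l1] += frac[k]
            data = np.moveaxis(
                np.tensordot(np.moveaxis(data, ax, 0), w, axes=(0, 0)), -1, ax
            )
        out = data
    if sigma_mm > 0:
        out = ndimage.gaussian_filter(out, sigma_mm / out_voxel, mode="nearest")
    return Volume(c * out, out_voxel)


def wls_weights(lines: np.ndarray, g: float = 1.0, eta: float = 3.0) -> np.ndarray:
    """Per-line-integral variance estimates q_i^2 = g exp(w_i / eta).

    The inverse of these variances weights the data-fidelity norm, so
    strongly attenuated (noisy) rays count less.
    """
    if g <= 0 or eta <= 0:
        raise ValueError("g and eta must be positive")
    return g * np.exp(np.asarray(lines, dtype=float) / eta)
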