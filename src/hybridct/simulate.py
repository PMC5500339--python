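"""Spectral projection synthesis with a photon-counting noise model.

For each energy channel the detected signal along a ray is the
spectrum-weighted transmission of the material line integrals,

    I = \\int I_D(e) exp(-sum_m mu_m(e) P_m) de,

with ``P_m`` the per-material path (concentration times length).  The
material density maps are first blurred with the chain's Gaussian point
spread function and resampled onto the chain's voxel grid, so each
chain sees the phantom at its own resolution; counts are then drawn
Poisson with mean I per detector cell.  Output sinograms are
gain-corrected, log-transformed line integrals ``y = ln(I_air / I)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import SystemGeometry, Volume, forward_project
from .phantom import FractionMaps
from .spectral import EnergyGrid, MaterialAttenuationTable

__all__ = ["ProjectionSet", "DetectorDefects", "synthesize_projections"]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class DetectorDefects:
    """Optional planted detector pathologies (for preprocessing tests)."""

    dead_fraction: float = 0.0  # fraction of stuck-low detector cells
    dead_gain: float = 0.3  # relative response of a dead cell
    ring_bias_sd: float = 0.0  # per-column multiplicative gain spread
    gap_columns: tuple = ()  # detector column indices reading zero


@dataclass
class ProjectionSet:
    """Log line integrals for one chain, one entry per energy channel."""

    y: np.ndarray  # (n_channels, *sino_shape)
    channels: list  # threshold keV per channel, or ["EID"]
    geometry: SystemGeometry
    air_counts: np.ndarray  # detected air signal per channel
    flux: float  # photons / line integral entering the chain
    n_clamped: int = 0
    defects: DetectorDefects | None = None
    brightfield: np.ndarray | None = None  # per-cell air counts (with gains)

    def __post_init__(self):
        if self.y.shape[0] != len(self.channels):
            raise ValueError("channel count mismatch")
        if tuple(self.y.shape[1:]) != self.geometry.sino_shape:
            raise ValueError("sinogram shape does not match geometry")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite line integrals")


def _resample_fractions(maps: FractionMaps, voxel: float, shape3) -> np.ndarray:
    """Trilinear resampling of fraction maps onto a chain's voxel grid."""
    if abs(voxel - maps.voxel_size) < 1e-12 and maps.fractions.shape[1:] == tuple(shape3):
        return maps.fractions.copy()
    out = np.empty((maps.fractions.shape[0], *shape3))
    coords = np.meshgrid(
        *[
            (np.arange(n) + 0.5 - n / 2.0) * voxel / maps.voxel_size
            + m / 2.0
            - 0.5
            for n, m in zip(shape3, maps.fractions.shape[1:])
        ],
        indexing="ij",
    )
    pts = np.stack([c.ravel() for c in coords])
    for i in range(out.shape[0]):
        out[i] = ndimage.map_coordinates(
            maps.fractions[i], pts, order=1, mode="constant", cval=0.0
        ).reshape(shape3)
    return out


def synthesize_projections(
    fractions: FractionMaps,
    geom: SystemGeometry,
    att: MaterialAttenuationTable,
    detected: list[np.ndarray],
    channels: list,
    flux: float,
    psf_fwhm_mm: float,
    seed: int | None = 0,
    noise: bool = True,
    detected_open: np.ndarray | None = None,
    defects: DetectorDefects | None = None,
    aperture_subsamples: int = 3,
) -> ProjectionSet:
    """Simulate gain-corrected log projections for one imaging chain.

    ``detected`` holds the detected-weight function I_D(e) per channel;
    ``detected_open`` is the unthresholded detected spectrum used to
    normalize the photon budget (defaults to the first channel), so
    ``flux`` is the photons per line integral entering the chain before
    energy thresholding.  ``psf_fwhm_mm`` is the chain PSF referred to
    the isocenter plane.  ``aperture_subsamples`` rays per detector
    cell model the cell's aperture integration (counts from across the
    cell add physically before the log transform).
    """
    if flux <= 0:
        raise ValueError("flux must be positive")
    grid: EnergyGrid = att.grid
    if geom.mode == "fan3d":
        shape3 = geom.vol_shape
    else:
        shape3 = (1, *geom.vol_shape)
    # chain PSF: blur the density maps at the phantom grid, then resample
    src = fractions
    if psf_fwhm_mm > 0:
        sig_vox = psf_fwhm_mm / _FWHM_TO_SIGMA / fractions.voxel_size
        sig = [0.0, sig_vox, sig_vox] if fractions.fractions.shape[1] < 4 else [sig_vox] * 3
        blurred = np.stack(
            [ndimage.gaussian_filter(f, sig, mode="nearest") for f in fractions.fractions]
        )
        bsupport = ndimage.gaussian_filter(
            fractions.support.astype(float), sig, mode="nearest"
        )
        src = FractionMaps(
            fractions=blurred,
            materials=fractions.materials,
            voxel_size=fractions.voxel_size,
            max_concentration=dict(fractions.max_concentration),
        )
        src._support = bsupport
    frac = _resample_fractions(src, geom.voxel_size, shape3)

    # per-material path lengths (mg/ml * mm for solutes, mm for water),
    # sub-sampled across the detector cell aperture
    mats = fractions.materials
    support = _resample_fractions(
        FractionMaps(
            fractions=src.support[None].astype(float),
            materials=("water",),
            voxel_size=src.voxel_size,
            max_concentration={"water": 1.0},
        ),
        geom.voxel_size,
        shape3,
    )[0]
    if aperture_subsamples < 1:
        raise ValueError("aperture_subsamples must be >= 1")
    sub_offsets = (
        (np.arange(aperture_subsamples) + 0.5) / aperture_subsamples - 0.5
        if aperture_subsamples > 1
        else np.array([0.0])
    )
    paths_by_offset = []
    for off in sub_offsets:
        paths = {}
        for i, m in enumerate(mats):
            conc = frac[i] * fractions.max_concentration[m]
            vol = conc if geom.mode == "fan3d" else conc[0]
            paths[m] = forward_project(Volume(vol, geom.voxel_size), geom, off)
        wvol = support if geom.mode == "fan3d" else support[0]
        paths["water"] = forward_project(Volume(wvol, geom.voxel_size), geom, off)
        paths_by_offset.append(paths)

    mu_sol = {m: att.mu_rho_on_grid(m) * 1e-4 for m in mats}  # mm^-1 per mg/ml
    mu_w = att.mu_on_grid("water")  # mm^-1

    open_weight = detected[0] if detected_open is None else detected_open
    kappa = flux / grid.integrate(open_weight)
    e = grid.energies
    de = np.gradient(e)
    trap_w = de.copy()
    trap_w[0] *= 0.5
    trap_w[-1] *= 0.5

    rng = np.random.default_rng(seed)

    y_all = np.empty((len(channels), *geom.sino_shape))
    air_counts = np.empty(len(channels))
    n_clamped = 0
    brightfield = None
    for ci, w in enumerate(detected):
        mean = np.zeros(geom.sino_shape)
        for paths in paths_by_offset:
            for k in range(e.size):
                a = mu_w[k] * paths["water"]
                for m in mats:
                    a = a + mu_sol[m][k] * paths[m]
                mean += (kappa / len(paths_by_offset) * trap_w[k] * w[k]) * np.exp(-a)
        air = kappa * grid.integrate(w)
        if defects is not None:
            mean, gain = _apply_defects(mean, air, defects, rng, geom)
            if brightfield is None:
                brightfield = air * gain
        counts = rng.poisson(np.maximum(mean, 0.0)).astype(float) if noise else mean
        low = counts < 1.0
        n_clamped += int(low.sum())
        counts = np.maximum(counts, 1.0)
        y_all[ci] = np.log(air / counts)
        air_counts[ci] = air
    return ProjectionSet(
        y=y_all,
        channels=list(channels),
        geometry=geom,
        air_counts=air_counts,
        flux=flux,
        n_clamped=n_clamped,
        defects=defects,
        brightfield=brightfield,
    )


def _apply_defects(mean, air, defects: DetectorDefects, rng, geom):
    """Apply planted per-detector-cell gains/gaps to the mean counts.

    The log transform still normalizes by the defect-free air signal
    (the calibration is assumed blind to the planted pathology), so
    defective cells appear as fixed-pattern log offsets — the artifact
    source the preprocessing module removes.  Returns the scaled mean
    counts and the per-cell bright-field gains.
    """
    n_det = mean.shape[-1]
    gain = np.ones(n_det)
    if defects.ring_bias_sd > 0:
        gain *= np.exp(rng.normal(0.0, defects.ring_bias_sd, size=n_det))
    if defects.dead_fraction > 0:
        n_dead = max(1, int(round(defects.dead_fraction * n_det)))
        dead = rng.choice(n_det, size=n_dead, replace=False)
        gain[dead] *= defects.dead_gain
    for col in defects.gap_columns:
        gain[col] = 0.0
    return mean * gain, gain
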