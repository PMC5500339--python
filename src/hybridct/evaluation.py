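"""Quantitative image-quality metrics.

Covers Hounsfield conversion, global RMSE against the expected
(noise-free, PSF-blurred) reconstruction, ROI bias, bar-pattern
modulation transfer with a single-parameter Gaussian MTF fit, and a
non-prewhitening detectability index over lesion ROIs.

DFT convention: all spectral quantities in the detectability index use
the unitary DFT; absolute index values depend on this convention but
the hybrid / PCD-only ratios used for comparisons do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .phantom import PhantomLayout

__all__ = [
    "hu_convert",
    "rmse",
    "roi_bias",
    "modulation_transfer",
    "measure_mt_table",
    "fit_mtf",
    "detectability_index",
    "MetricsReport",
]


def hu_convert(vol: np.ndarray, mu_water: float) -> np.ndarray:
    """Attenuation (mm^-1) to Hounsfield units for one energy channel."""
    if mu_water <= 0:
        raise ValueError("water attenuation must be positive")
    return 1000.0 * (np.asarray(vol, dtype=float) - mu_water) / mu_water


def rmse(vol: np.ndarray, truth: np.ndarray) -> float:
    """Root-mean-square voxel error against the expected reconstruction."""
    vol = np.asarray(vol, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if vol.shape != truth.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.mean((vol - truth) ** 2)))


def roi_bias(vol: np.ndarray, roi: np.ndarray, expected: float) -> float:
    """Absolute deviation of the ROI mean from its expected value."""
    roi = np.asarray(roi)
    if roi.dtype == bool:
        vals = np.asarray(vol)[roi]
    else:
        vals = np.asarray(vol)[tuple(roi)]
    if vals.size == 0:
        raise ValueError("empty ROI")
    return float(abs(vals.mean() - expected))


def modulation_transfer(a: float, b: float, water_ref: float = 0.0) -> float:
    """MT = |a - b| / (a + b) on water-subtracted bar/gap means.

    ``a`` and ``b`` are mean attenuations over the expected bar and gap
    locations; negative values are clipped to zero.
    """
    aa = a - water_ref
    bb = b - water_ref
    denom = aa + bb
    if denom == 0:
        return 0.0
    return float(max(0.0, abs(aa - bb) / denom))


def measure_mt_table(
    volumes: dict, layout: PhantomLayout, water_ref: dict
) -> list[dict]:
    """MT for every (bar group, disk, channel) in the phantom layout.

    ``volumes`` maps channel label -> reconstructed volume (nz, ny, nx);
    ``water_ref`` maps channel label -> expected water attenuation.
    Returns one record per measurement: the full-phantom design yields
    8 frequencies x 3 disks x 5 thresholds = 120 entries.
    """
    records = []
    for label, vol in volumes.items():
        w = water_ref[label]
        for g in layout.bar_groups:
            bars = np.concatenate([vol[s].ravel() for s in g.bar_slices])
            gaps = np.concatenate([vol[s].ravel() for s in g.gap_slices])
            records.append(
                {
                    "channel": label,
                    "disk": g.disk,
                    "frequency": g.frequency,
                    "mt": modulation_transfer(bars.mean(), gaps.mean(), w),
                }
            )
    return records


def fit_mtf(frequencies: np.ndarray, mt_values: np.ndarray) -> float:
    """Least-squares fit of the single-parameter Gaussian MTF.

    Fits ``MTF(l) = exp(-l^2 / (2 sigma^2))`` and returns ``sigma`` in
    the units of the frequency axis (lp/mm).  All-zero measurements are
    degenerate; all-one measurements are an unresolved limit and return
    infinity.
    """
    l = np.asarray(frequencies, dtype=float)
    n = np.asarray(mt_values, dtype=float)
    if np.unique(l).size < 2:
        raise ValueError("need at least two distinct frequencies")
    if np.all(n <= 0):
        raise ValueError("all MT values are zero; nothing to fit")
    if np.all(n >= 1.0 - 1e-12):
        return np.inf
    # initialize from the first frequency that falls below 1/2
    below = n < 0.5
    l0 = l[below].min() if below.any() else l.max()
    x0 = max(l0 / 1.1774, 1e-3)
    res = least_squares(
        lambda s: np.exp(-(l**2) / (2.0 * s[0] ** 2)) - n,
        x0=[x0],
        bounds=([1e-6], [np.inf]),
    )
    return float(res.x[0])


def _radial_freq(shape: tuple, voxel_size: float) -> np.ndarray:
    """Radial spatial frequency (lp/mm) of each DFT bin."""
    axes = [np.fft.fftfreq(n, d=voxel_size) for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(sum(g * g for g in grids))


def detectability_index(
    recon_roi: np.ndarray,
    truth_roi: np.ndarray,
    mtf_sigma: float,
    water_ref: float,
    voxel_size: float,
) -> float:
    """Non-prewhitening observer detectability for one lesion ROI.

    The task function W is the unitary DFT of the water-subtracted
    expected lesion; the noise power spectrum is the power spectral
    density of (recon - truth) inside the same ROI; the 1D Gaussian MTF
    is extrapolated isotropically over the DFT radius.
    """
    recon_roi = np.asarray(recon_roi, dtype=float)
    truth_roi = np.asarray(truth_roi, dtype=float)
    if recon_roi.shape != truth_roi.shape:
        raise ValueError("ROI shapes differ")
    n = recon_roi.size
    w = np.fft.fftn(truth_roi - water_ref, norm="ortho")
    nps = np.abs(np.fft.fftn(recon_roi - truth_roi, norm="ortho")) ** 2
    freq = _radial_freq(recon_roi.shape, voxel_size)
    if np.isinf(mtf_sigma):
        mtf = np.ones_like(freq)
    else:
        mtf = np.exp(-(freq**2) / (2.0 * mtf_sigma**2))
    tw2 = (mtf * np.abs(w)) ** 2
    num = tw2.sum() ** 2
    den = (nps * tw2).sum()
    if den <= 0:
        return np.inf if num > 0 else 0.0
    return float(num / den)


@dataclass
class MetricsReport:
    """Collected per-channel metrics for one reconstruction."""

    rmse_hu: dict = field(default_factory=dict)
    vial_bias_hu: dict = field(default_factory=dict)  # (channel, material) -> HU
    vial_sd_hu: dict = field(default_factory=dict)
    mt_table: list = field(default_factory=list)
    mtf_sigma: float | None = None
    detectability: dict = field(default_factory=dict)  # lesion id -> index

    def as_records(self) -> list[dict]:
        recs = [{"metric": "mtf_sigma", "value": self.mtf_sigma}]
        recs += [
            {"metric": "rmse_hu", "channel": c, "value": v}
            for c, v in self.rmse_hu.items()
        ]
        recs += [
            {"metric": "vial_bias_hu", "channel": c, "material": m, "value": v}
            for (c, m), v in self.vial_bias_hu.items()
        ]
        recs += [
            {"metric": "vial_sd_hu", "channel": c, "material": m, "value": v}
            for (c, m), v in self.vial_sd_hu.items()
        ]
        recs += [dict(r, metric="mt") for r in self.mt_table]
        recs += [
            {"metric": "detectability", "lesion": k, "value": v}
            for k, v in self.detectability.items()
        ]
        return recs
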