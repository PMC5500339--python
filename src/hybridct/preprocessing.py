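"""PCD projection preprocessing: the three detector corrections.

Applied, in order, to log-transformed photon-counting sinograms before
reconstruction: (1) outlier-pixel interpolation (ring-artifact
prevention), (2) ring-bias correction, (3) detector-gap interpolation.
All corrections operate on one energy channel at a time and never mix
channels.  Sinogram borders are handled by edge replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DetectorMask",
    "flag_outlier_pixels",
    "interpolate_flagged",
    "ring_bias_correct",
    "interpolate_gaps",
    "preprocess_sinogram",
]

GOOD, OUTLIER, GAP = 0, 1, 2


@dataclass
class DetectorMask:
    """Per-detector-pixel status flags (good / outlier / gap)."""

    flags: np.ndarray  # int array over detector cells

    @property
    def outliers(self) -> np.ndarray:
        return self.flags == OUTLIER

    @property
    def gaps(self) -> np.ndarray:
        return self.flags == GAP


def flag_outlier_pixels(
    brightfield: np.ndarray, threshold_frac: float = 0.25
) -> DetectorMask:
    """Flag detector cells deviating from the median air signal.

    Cells whose bright-field signal differs from the median by more
    than ``threshold_frac`` (relative) are marked as outliers.
    """
    bf = np.asarray(brightfield, dtype=float)
    if np.any(bf < 0):
        raise ValueError("brightfield must be nonnegative")
    med = np.median(bf)
    if med <= 0:
        raise ValueError("degenerate brightfield (nonpositive median)")
    flags = np.where(np.abs(bf - med) / med > threshold_frac, OUTLIER, GOOD)
    if np.all(flags == OUTLIER):
        raise ValueError("all pixels flagged; brightfield is degenerate")
    return DetectorMask(flags=flags.astype(np.int8))


def interpolate_flagged(
    sino: np.ndarray, mask: DetectorMask, sigma: float = 1.0
) -> np.ndarray:
    """Inpaint outlier detector cells per projection angle.

    ``sino`` has shape (n_views, n_det); the mask indexes the detector
    axis.  Each angle is treated independently with a 1D normalized
    Gaussian kernel over the detector dimension (the 2D detector
    collapses to one row per angle in fan-beam desk mode).
    """
    sino = np.asarray(sino, dtype=float)
    bad = np.broadcast_to(mask.outliers, sino.shape)
    if not bad.any():
        return sino.copy()
    good = (~bad).astype(float)
    vals = np.where(bad, 0.0, sino)
    num = ndimage.gaussian_filter1d(vals, sigma, axis=-1, mode="nearest")
    den = ndimage.gaussian_filter1d(good, sigma, axis=-1, mode="nearest")
    if np.any(bad & (den <= 1e-12)):
        raise ValueError("flagged region exceeds interpolation kernel support")
    out = sino.copy()
    out[bad] = num[bad] / den[bad]
    return out


def ring_bias_correct(sino: np.ndarray, box_len: int = 5) -> np.ndarray:
    """Remove fixed-pattern detector bias estimated by dual low-pass filtering.

    For every detector cell, the correction is the mean over angles of
    the difference between the sinogram smoothed along the detector
    axis and smoothed along the angular axis (1D box filters of
    ``box_len``).  The applied correction is clipped per angle so its
    magnitude never exceeds the uncorrected magnitude.
    """
    sino = np.asarray(sino, dtype=float)
    if box_len % 2 != 1:
        raise ValueError("box_len must be odd")
    if box_len > min(sino.shape):
        raise ValueError("box_len exceeds sinogram dimensions")
    lp_det = ndimage.uniform_filter1d(sino, box_len, axis=-1, mode="nearest")
    lp_ang = ndimage.uniform_filter1d(sino, box_len, axis=0, mode="nearest")
    bias = np.mean(lp_ang - lp_det, axis=0, keepdims=True)
    correction = np.clip(np.broadcast_to(bias, sino.shape), -np.abs(sino), np.abs(sino))
    return sino - correction


def interpolate_gaps(
    sino: np.ndarray,
    mask: DetectorMask,
    kernel_diameter: int = 41,
    kernel_sigma: float = 8.0,
) -> np.ndarray:
    """Fill detector-gap bands by 1D normalized Gaussian interpolation.

    Interpolation runs perpendicular to the gap orientation, i.e. along
    the detector axis for the column gaps modeled here.
    """
    sino = np.asarray(sino, dtype=float)
    gaps = np.broadcast_to(mask.gaps, sino.shape)
    if not gaps.any():
        return sino.copy()
    reach = kernel_diameter // 2
    gap_cols = np.where(mask.gaps)[0]
    runs = np.split(gap_cols, np.where(np.diff(gap_cols) > 1)[0] + 1)
    if any(len(r) > 2 * reach for r in runs):
        raise ValueError("gap band wider than the interpolation kernel reach")
    good = (~gaps).astype(float)
    vals = np.where(gaps, 0.0, sino)
    num = ndimage.gaussian_filter1d(vals, kernel_sigma, axis=-1, mode="nearest", truncate=reach / kernel_sigma)
    den = ndimage.gaussian_filter1d(good, kernel_sigma, axis=-1, mode="nearest", truncate=reach / kernel_sigma)
    if np.any(gaps & (den <= 1e-12)):
        raise ValueError("gap band wider than the interpolation kernel reach")
    out = sino.copy()
    out[gaps] = num[gaps] / den[gaps]
    return out


def preprocess_sinogram(
    sino: np.ndarray,
    mask: DetectorMask | None = None,
    outlier_sigma: float = 1.0,
    box_len: int = 5,
    gap_kernel_diameter: int = 41,
    gap_kernel_sigma: float = 8.0,
) -> np.ndarray:
    """Apply the three corrections in their fixed order to one channel.

    Gap columns carry no signal, so they are provisionally filled
    before the ring-bias estimation (and re-interpolated afterwards);
    otherwise their bogus values leak into the bias estimate of their
    neighbors.
    """
    out = np.asarray(sino, dtype=float).copy()
    has_gaps = mask is not None and mask.gaps.any()
    if mask is not None and mask.outliers.any():
        out = interpolate_flagged(out, mask, sigma=outlier_sigma)
    if has_gaps:
        out = interpolate_gaps(
            out, mask, kernel_diameter=gap_kernel_diameter, kernel_sigma=gap_kernel_sigma
        )
    out = ring_bias_correct(out, box_len=box_len)
    if has_gaps:
        out = interpolate_gaps(
            out, mask, kernel_diameter=gap_kernel_diameter, kernel_sigma=gap_kernel_sigma
        )
    return out
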