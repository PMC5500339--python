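"""Per-voxel material decomposition and recomposition.

Energy-channel attenuation stacks are inverted to basis-material
concentration maps (photoelectric, Compton, iodine, barium) by linear
least squares through the pseudo-inverse of the material sensitivity
matrix.  The optional non-negativity constraint is solved exactly by
exhaustive active-set search over the 2^n_m sign patterns, which is
cheap for n_m = 4 and returns the true constrained minimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .spectral import MaterialSensitivityMatrix

__all__ = ["ConcentrationMaps", "decompose", "recompose"]


@dataclass
class ConcentrationMaps:
    """Basis-material volumes: mg/ml for iodine/barium, water-relative
    coefficients for the PE/CS components (pure water = 1, 1)."""

    maps: np.ndarray  # (n_materials, *spatial)
    materials: tuple

    def get(self, name: str) -> np.ndarray:
        return self.maps[self.materials.index(name)]


def _sensitivity_rows(m: np.ndarray | MaterialSensitivityMatrix):
    if isinstance(m, MaterialSensitivityMatrix):
        return m.m, m.materials
    return np.asarray(m, dtype=float), None


def decompose(
    x: np.ndarray,
    m: np.ndarray | MaterialSensitivityMatrix,
    nonneg: bool = False,
) -> ConcentrationMaps:
    """Invert per-voxel attenuation across channels into concentrations.

    ``x`` is (n_channels, *spatial).  The unconstrained solution is the
    least-squares fit through the pseudo-inverse; with ``nonneg`` every
    voxel whose unconstrained fit has a negative component is re-solved
    over all feasible active sets and the lowest-residual nonnegative
    candidate wins.
    """
    mat, names = _sensitivity_rows(m)
    n_e, n_m = mat.shape
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] != n_e:
        raise ValueError("channel count does not match sensitivity rows")
    if np.linalg.matrix_rank(mat) < n_m:
        raise np.linalg.LinAlgError("rank-deficient material sensitivity matrix")
    spatial = x.shape[1:]
    xv = x.reshape(n_e, -1)
    pinv = np.linalg.pinv(mat)
    c = pinv @ xv  # (n_m, n_vox)
    if nonneg:
        bad = np.any(c < 0, axis=0)
        if bad.any():
            xb = xv[:, bad]
            best_c = np.zeros((n_m, xb.shape[1]))
            best_r = np.einsum("ij,ij->j", xb, xb)  # empty active set
            for k in range(1, n_m + 1):
                for sel in combinations(range(n_m), k):
                    sub = mat[:, sel]
                    cs = np.linalg.pinv(sub) @ xb
                    feasible = np.all(cs >= 0, axis=0)
                    if not feasible.any():
                        continue
                    res = xb - sub @ cs
                    r = np.einsum("ij,ij->j", res, res)
                    better = feasible & (r < best_r - 1e-15 * np.maximum(best_r, 1.0))
                    if better.any():
                        best_r[better] = r[better]
                        best_c[:, better] = 0.0
                        for i, s in enumerate(sel):
                            best_c[s, better] = cs[i, better]
            c[:, bad] = best_c
        c = np.maximum(c, 0.0)
    names = names or tuple(f"m{i}" for i in range(n_m))
    return ConcentrationMaps(maps=c.reshape(n_m, *spatial), materials=tuple(names))


def recompose(c: ConcentrationMaps, sensitivities: np.ndarray) -> np.ndarray:
    """Per-voxel dot product of concentrations with one channel's
    material sensitivities (e.g. the EID row for component
    substitution)."""
    s = np.asarray(sensitivities, dtype=float)
    if s.shape != (c.maps.shape[0],):
        raise ValueError("sensitivity vector length does not match materials")
    return np.tensordot(s, c.maps, axes=(0, 0))
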