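"""Patch-dictionary learning (K-SVD) and sparse-coding denoising (OMP).

Patches are radial (spherical) 3D neighborhoods; each patch is
mean-subtracted before coding and the mean is strictly restored
afterwards, so sparse coding cannot introduce spectral bias.  The
dictionary is trained once on a high-quality volume (the EID filtered
backprojection in the hybrid pipeline) and then reused to code every
channel; the coding stop rule is the noise-calibrated residual
criterion ``||r||^2 <= n_v * MAD(tile(vol, s))^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regularization import estimate_noise_mad, sphere_offsets, tile

__all__ = ["DictionaryModel", "extract_patches", "ksvd", "learn_dictionary", "omp_denoise"]


@dataclass
class DictionaryModel:
    """Overcomplete dictionary of unit-norm, zero-mean radial patch atoms."""

    atoms: np.ndarray  # (n_voxels_per_patch, n_atoms)
    offsets: np.ndarray  # (n_voxels_per_patch, ndim) integer offsets
    patch_radius: int
    noise_level: float = 0.0  # training-phase noise sigma

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    def __post_init__(self):
        if self.atoms.size == 0:
            raise ValueError("empty dictionary")

    def save(self, path):
        """Serialize atoms and patch geometry to HDF5."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("atoms", data=self.atoms)
            f.create_dataset("offsets", data=self.offsets)
            f.attrs["patch_radius"] = self.patch_radius
            f.attrs["noise_level"] = self.noise_level

    @classmethod
    def load(cls, path) -> "DictionaryModel":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                atoms=f["atoms"][()],
                offsets=f["offsets"][()],
                patch_radius=int(f.attrs["patch_radius"]),
                noise_level=float(f.attrs["noise_level"]),
            )


def _patch_matrix(vol: np.ndarray, offsets: np.ndarray, centers: np.ndarray):
    """Gather patches (n_voxels, n_centers) at the given center indices."""
    idx = centers[:, None, :] + offsets[None, :, :]  # (n_c, n_v, ndim)
    flat = np.ravel_multi_index(
        tuple(np.moveaxis(idx, -1, 0)), vol.shape, mode="clip"
    )
    return vol.ravel()[flat].T  # (n_v, n_c)


def _interior_centers(shape: tuple, radius: int) -> np.ndarray:
    axes = [np.arange(radius, n - radius) for n in shape]
    if any(a.size == 0 for a in axes):
        raise ValueError("volume too small for the requested patch radius")
    grids = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def extract_patches(
    vol: np.ndarray, radius: int, centers: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (or selected) overlapping radial patches as columns.

    Returns (patches, offsets, centers); patches retain their means.
    """
    vol = np.asarray(vol, dtype=np.float64)
    offsets = sphere_offsets(radius, vol.ndim)
    if centers is None:
        centers = _interior_centers(vol.shape, radius)
    return _patch_matrix(vol, offsets, centers), offsets, centers


def _omp_batch(
    patches: np.ndarray,
    atoms: np.ndarray,
    n0: int,
    eps: float,
) -> np.ndarray:
    """Batch orthogonal matching pursuit with progressive Cholesky.

    ``patches`` (n_v, n_p) are mean-free.  Stops per patch when the
    residual energy drops to ``eps`` or ``n0`` atoms are used.  Returns
    the dense coefficient matrix (n_atoms, n_p).  Ties on the
    correlation maximum resolve to the lowest atom index (argmax).
    """
    n_v, n_p = patches.shape
    n_a = atoms.shape[1]
    gram = atoms.T @ atoms
    proj0 = atoms.T @ patches  # (n_a, n_p)
    coefs = np.zeros((n_a, n_p))
    support = np.full((n0, n_p), -1, dtype=np.int64)
    n_sel = np.zeros(n_p, dtype=np.int64)
    alpha = proj0.copy()
    energy = np.einsum("ij,ij->j", patches, patches)
    res_energy = energy.copy()
    gamma = np.zeros((n0, n_p))
    active = res_energy > eps
    for k in range(n0):
        if not active.any():
            break
        ai = np.flatnonzero(active)
        # lowest-index tie-break is argmax's native behavior
        support[k, ai] = np.argmax(np.abs(alpha[:, ai]), axis=0)
        n_sel[ai] = k + 1
        sel = support[: k + 1, ai]  # (k+1, n_active)
        # batched normal-equation solve on each patch's support
        gsub = gram[sel.T[:, :, None], sel.T[:, None, :]]
        gsub = gsub + 1e-12 * np.eye(k + 1)[None]
        rhs = np.take_along_axis(proj0[:, ai], sel, axis=0).T[:, :, None]
        sol = np.linalg.solve(gsub, rhs)[:, :, 0]  # (n_active, k+1)
        gamma[: k + 1, ai] = sol.T
        # residual correlations: alpha = proj0 - G[:, sel] @ gamma
        recon = np.zeros((n_a, ai.size))
        for j in range(k + 1):
            recon += gram[:, sel[j]] * sol[:, j][None, :]
        alpha[:, ai] = proj0[:, ai] - recon
        # selected atoms are orthogonal to the residual by construction;
        # zero them explicitly so round-off never re-picks one
        for j in range(k + 1):
            alpha[sel[j], ai] = 0.0
        res_energy[ai] = energy[ai] - np.einsum(
            "ka,ka->a", np.take_along_axis(proj0[:, ai], sel, axis=0), sol.T
        )
        active[ai] = res_energy[ai] > np.maximum(eps, energy[ai] * 1e-10)
    for p in np.flatnonzero(n_sel):
        k = n_sel[p]
        coefs[support[:k, p], p] = gamma[:k, p]
    return coefs


def ksvd(
    pool: np.ndarray,
    n_atoms: int,
    n_iterations: int,
    n0: int,
    eps: float,
    rng: np.random.Generator,
    n_restarts: int = 1,
) -> np.ndarray:
    """K-SVD on a pool of mean-free training patches (columns).

    Alternates OMP sparse coding with sequential rank-1 atom updates;
    under-used or near-duplicate atoms are replaced by the worst-coded
    training patches.  K-SVD has local minima (occasionally one atom
    converges onto a mixture of two underlying components), so the
    training is restarted from ``n_restarts`` initializations and the
    dictionary with the lowest coding residual is kept.  Returns the
    unit-norm, zero-mean atom matrix.
    """
    if n_restarts > 1:
        best = (np.inf, None)
        for child in rng.spawn(n_restarts):
            atoms = ksvd(pool, n_atoms, n_iterations, n0, eps, child, n_restarts=1)
            coefs = _omp_batch(pool, atoms, n0, eps)
            res = float(np.linalg.norm(pool - atoms @ coefs) ** 2)
            if res < best[0]:
                best = (res, atoms)
        return best[1]
    n_v = pool.shape[0]
    if pool.shape[1] < n_atoms:
        raise ValueError("fewer candidate patches than atoms")
    init_idx = rng.choice(pool.shape[1], n_atoms, replace=False)
    atoms = pool[:, init_idx].copy()
    atoms -= atoms.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(atoms, axis=0)
    atoms /= np.where(norms > 1e-12, norms, 1.0)

    for _ in range(n_iterations):
        coefs = _omp_batch(pool, atoms, n0, eps)
        # dictionary update, one atom at a time (approximate K-SVD)
        residual = pool - atoms @ coefs
        err_per_patch = np.einsum("ij,ij->j", residual, residual)
        usage = (np.abs(coefs) > 0).sum(axis=1)
        for a in range(n_atoms):
            users = np.nonzero(coefs[a])[0]
            if users.size == 0:
                continue
            # rank-1 update of atom a over its users
            r = residual[:, users] + np.outer(atoms[:, a], coefs[a, users])
            u = r @ coefs[a, users]
            u -= u.mean()
            nrm = np.linalg.norm(u)
            if nrm <= 1e-12:
                continue
            u /= nrm
            new_c = u @ r
            residual[:, users] = r - np.outer(u, new_c)
            atoms[:, a] = u
            coefs[a, users] = new_c
        # replace under-used or duplicate atoms with worst-coded patches
        gram = np.abs(atoms.T @ atoms) - np.eye(n_atoms)
        worst = np.argsort(err_per_patch)[::-1]
        wi = 0
        for a in range(n_atoms):
            if usage[a] < 2 or gram[a].max() > 0.99:
                cand = pool[:, worst[wi % worst.size]].copy()
                wi += 1
                cand -= cand.mean()
                nrm = np.linalg.norm(cand)
                if nrm > 1e-12:
                    atoms[:, a] = cand / nrm
    return atoms


def learn_dictionary(
    vol: np.ndarray,
    n_atoms: int = 1024,
    patch_radius: int = 4,
    n_train: int = 500_000,
    n_iterations: int = 25,
    n0: int = 48,
    stride: int = 3,
    seed: int | None = 0,
) -> DictionaryModel:
    """K-SVD dictionary learning on patches of one volume.

    Training patches are drawn from all overlapping radial patches with
    variance above the (tiling-robust) MAD noise level; under-used or
    duplicate atoms are replaced by poorly represented patches.
    """
    vol = np.asarray(vol, dtype=np.float64)
    rng = np.random.default_rng(seed)
    sigma = estimate_noise_mad(tile(vol, stride))
    patches, offsets, centers = extract_patches(vol, patch_radius)
    n_v = patches.shape[0]
    means = patches.mean(axis=0, keepdims=True)
    patches = patches - means
    var = np.einsum("ij,ij->j", patches, patches) / n_v
    good = var > sigma**2
    if not good.any():
        raise ValueError("no patches pass the variance screen (constant volume?)")
    pool = patches[:, good]
    if pool.shape[1] > n_train:
        pool = pool[:, rng.choice(pool.shape[1], n_train, replace=False)]
    atoms = ksvd(pool, n_atoms, n_iterations, n0, n_v * sigma**2, rng)
    return DictionaryModel(
        atoms=atoms, offsets=offsets, patch_radius=patch_radius, noise_level=sigma
    )


def omp_denoise(
    vol: np.ndarray,
    model: DictionaryModel,
    n0_max: int = 5,
    stride: int = 3,
    batch: int = 20000,
) -> np.ndarray:
    """Sparse-code every overlapping patch and average the overlaps.

    Patch means are subtracted before coding and restored afterwards,
    so the volume mean is preserved; zero-variance patches skip coding.
    The per-patch stop rule is the noise-calibrated residual criterion.
    """
    orig = np.asarray(vol, dtype=np.float64)
    sigma = estimate_noise_mad(tile(orig, stride))
    offsets = model.offsets
    n_v = offsets.shape[0]
    eps = n_v * sigma**2
    # edge-pad so every original voxel sees the full overlapping-patch
    # coverage; with uniform coverage the per-patch mean preservation
    # carries over to the volume mean
    r = model.patch_radius
    vol = np.pad(orig, r, mode="edge")
    centers = _interior_centers(vol.shape, model.patch_radius)
    out = np.zeros_like(vol)
    weight = np.zeros_like(vol)
    for lo in range(0, centers.shape[0], batch):
        cen = centers[lo : lo + batch]
        patches = _patch_matrix(vol, offsets, cen)
        means = patches.mean(axis=0, keepdims=True)
        centered = patches - means
        if sigma > 0:
            coefs = _omp_batch(centered, model.atoms, n0_max, eps)
            coded = model.atoms @ coefs + means
        else:
            coded = patches
        idx = cen[:, None, :] + offsets[None, :, :]
        flat = np.ravel_multi_index(tuple(np.moveaxis(idx, -1, 0)), vol.shape)
        np.add.at(out.ravel(), flat.ravel(), coded.T.ravel())
        np.add.at(weight.ravel(), flat.ravel(), 1.0)
    uncovered = weight == 0
    out[uncovered] = vol[uncovered]
    weight[uncovered] = 1.0
    out = out / weight
    return out[tuple(slice(r, n - r) for n in vol.shape)]
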