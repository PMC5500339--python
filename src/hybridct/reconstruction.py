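"""Split Bregman hybrid reconstruction and the PCD-only control.

The hybrid problem jointly reconstructs X_L (redundant copies of the
high-resolution EID image) and X_S (the spectral contrast contributed
by the photon-counting channels) from two weighted least-squares data
fidelity terms,

    1/2 ||R x_L - w||_Q^2 + lambda_C/2 ||A B (x_L + x_S) - y_e||_Z^2,

with B the Gaussian blur/downsampling operator coupling the two chain
resolutions.  Rank and joint gradient-sparsity constraints are enforced
by alternating RSKR and dictionary sparse coding with add-residual-back
tracking; a single regularized estimate (D) and residual (V) pair is
kept after both regularizers.  The coupled per-energy normal equations
are solved by BiCGSTAB with fixed iteration counts and warm starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import LinearOperator, bicgstab

from . import dictionary as dict_mod
from .decomposition import ConcentrationMaps, decompose, recompose
from .geometry import (
    SystemGeometry,
    Volume,
    back_project,
    blur_downsample,
    blur_downsample_adjoint,
    fbp_reconstruct,
    forward_project,
    upsample_transpose,
    wls_weights,
)
from .regularization import (
    RegularizerConfig,
    estimate_noise_mad,
    rskr,
    tile,
)
from .simulate import ProjectionSet
from .spectral import MaterialSensitivityMatrix

__all__ = [
    "ReconConfig",
    "CalibratedParams",
    "SpectralVolumes",
    "HybridOperators",
    "component_substitution_init",
    "calibrate_params",
    "data_fidelity_update",
    "fidelity_objective",
    "hybrid_reconstruct",
    "pcd_only_reconstruct",
]


@dataclass
class ReconConfig:
    """Reconstruction parameters (defaults follow the published setup)."""

    lambda_c: float = 1.0  # hybrid data-fidelity balance, per channel
    alpha: float = 0.01  # regularization scaling factor in [0.001, 0.01]
    eta: float = 3.0  # WLS calibration (EID & PCD)
    g: float = 1.0
    bicg_init_iters: int = 30
    bicg_iters: int = 25
    n_bregman: int = 6
    bregman_tol: float = 0.01  # relative change of ||V|| that stops early
    reg: RegularizerConfig = field(default_factory=RegularizerConfig)
    seed: int = 0


@dataclass
class CalibratedParams:
    """Per-channel calibration derived from the initialized state."""

    sigma: np.ndarray  # MAD noise per channel
    delta: np.ndarray  # water-normalized noise ratios, min-normalized
    mu_l: np.ndarray
    mu_s: np.ndarray
    priority: np.ndarray  # p_e = 1 / (delta_e * mu_water_e)


@dataclass
class SpectralVolumes:
    """Solution state: paired stacks over the energy channels."""

    xl: np.ndarray  # (n_e, *shape)
    xs: np.ndarray
    channels: list
    voxel_size: float

    @property
    def x(self) -> np.ndarray:
        """High-resolution spectral estimate X = X_L + X_S."""
        return self.xl + self.xs


class HybridOperators:
    """The linear operators of one hybrid chain pair, desk-mode agnostic."""

    def __init__(
        self,
        geom_eid: SystemGeometry,
        geom_pcd: SystemGeometry,
        sigma_r: float,
    ):
        self.geom_eid = geom_eid
        self.geom_pcd = geom_pcd
        self.sigma_r = sigma_r
        self.shape_hi = tuple(geom_eid.vol_shape)
        self.shape_lo = tuple(geom_pcd.vol_shape)
        self.dv_hi = geom_eid.voxel_size
        self.dv_lo = geom_pcd.voxel_size

    # --- projectors -------------------------------------------------
    def r(self, x: np.ndarray) -> np.ndarray:
        return forward_project(Volume(x, self.dv_hi), self.geom_eid)

    def rt(self, s: np.ndarray) -> np.ndarray:
        return back_project(s, self.geom_eid).data

    def a(self, x_lo: np.ndarray) -> np.ndarray:
        return forward_project(Volume(x_lo, self.dv_lo), self.geom_pcd)

    def at(self, s: np.ndarray) -> np.ndarray:
        return back_project(s, self.geom_pcd).data

    # --- resolution coupling ---------------------------------------
    def b(self, x_hi: np.ndarray) -> np.ndarray:
        return blur_downsample(
            Volume(x_hi, self.dv_hi), self.sigma_r, self.dv_lo, out_shape=self.shape_lo
        ).data

    def bt_adjoint(self, x_lo: np.ndarray) -> np.ndarray:
        return blur_downsample_adjoint(
            Volume(x_lo, self.dv_lo), self.sigma_r, self.dv_hi, out_shape=self.shape_hi
        ).data

    def bt_interp(self, x_lo: np.ndarray) -> np.ndarray:
        return upsample_transpose(
            Volume(x_lo, self.dv_lo), self.sigma_r, self.dv_hi, out_shape=self.shape_hi
        ).data


def fidelity_objective(ops, xl, xs, w, y_e, inv_q, inv_z, lam, mu_l, mu_s, dl, vl, ds, vs):
    """Energy-wise quadratic objective of the data-fidelity subproblem."""
    r1 = ops.r(xl) - w
    r2 = ops.a(ops.b(xl + xs)) - y_e
    val = 0.5 * np.sum(r1 * inv_q * r1) + 0.5 * lam * np.sum(r2 * inv_z * r2)
    val += 0.5 * mu_l * np.sum((xl + vl - dl) ** 2)
    val += 0.5 * mu_s * np.sum((xs + vs - ds) ** 2)
    return float(val)


def _solve_channel_hybrid(
    ops: HybridOperators,
    xl0: np.ndarray,
    xs0: np.ndarray,
    w: np.ndarray,
    y_e: np.ndarray,
    inv_q: np.ndarray,
    inv_z: np.ndarray,
    lam: float,
    mu_l: float,
    mu_s: float,
    rhs_l_extra: np.ndarray | None,
    rhs_s_extra: np.ndarray | None,
    n_iters: int,
) -> tuple[np.ndarray, np.ndarray]:
    """BiCGSTAB solve of the coupled per-energy normal equations."""
    n = int(np.prod(ops.shape_hi))

    def matvec(zv):
        xl = zv[:n].reshape(ops.shape_hi)
        xs = zv[n:].reshape(ops.shape_hi)
        common = ops.bt_adjoint(ops.at(inv_z * ops.a(ops.b(xl + xs)))) * lam
        row1 = ops.rt(inv_q * ops.r(xl)) + common + mu_l * xl
        row2 = common + mu_s * xs
        return np.concatenate([row1.ravel(), row2.ravel()])

    common_rhs = lam * ops.bt_adjoint(ops.at(inv_z * y_e))
    rhs1 = ops.rt(inv_q * w) + common_rhs
    rhs2 = common_rhs.copy()
    if rhs_l_extra is not None:
        rhs1 = rhs1 + mu_l * rhs_l_extra
    if rhs_s_extra is not None:
        rhs2 = rhs2 + mu_s * rhs_s_extra
    rhs = np.concatenate([rhs1.ravel(), rhs2.ravel()])
    op = LinearOperator((2 * n, 2 * n), matvec=matvec, dtype=np.float64)
    x0 = np.concatenate([xl0.ravel(), xs0.ravel()])
    sol, info = bicgstab(op, rhs, x0=x0, rtol=1e-12, atol=0.0, maxiter=n_iters)
    if info < 0 or not np.all(np.isfinite(sol)):
        # solver breakdown: restart from the warm-start state
        sol = x0
    return sol[:n].reshape(ops.shape_hi), sol[n:].reshape(ops.shape_hi)


def _solve_channel_pcd(
    ops: HybridOperators,
    x0v: np.ndarray,
    y_e: np.ndarray,
    inv_z: np.ndarray,
    lam: float,
    mu: float,
    rhs_extra: np.ndarray | None,
    n_iters: int,
) -> np.ndarray:
    n = int(np.prod(ops.shape_hi))

    def matvec(zv):
        x = zv.reshape(ops.shape_hi)
        out = lam * ops.bt_adjoint(ops.at(inv_z * ops.a(ops.b(x)))) + mu * x
        return out.ravel()

    rhs = lam * ops.bt_adjoint(ops.at(inv_z * y_e))
    if rhs_extra is not None:
        rhs = rhs + mu * rhs_extra
    op = LinearOperator((n, n), matvec=matvec, dtype=np.float64)
    sol, info = bicgstab(
        op, rhs.ravel(), x0=x0v.ravel(), rtol=1e-12, atol=0.0, maxiter=n_iters
    )
    if info < 0 or not np.all(np.isfinite(sol)):
        sol = x0v.ravel()
    return sol.reshape(ops.shape_hi)


def component_substitution_init(
    y_pcd: ProjectionSet,
    w_eid: ProjectionSet,
    msm: MaterialSensitivityMatrix,
    ops: HybridOperators,
) -> tuple[SpectralVolumes, np.ndarray]:
    """FBP + material decomposition initialization (component substitution).

    X_0 is the upsampled FBP of each PCD channel; decomposing X_0 and
    recomposing with the EID sensitivities gives the low-resolution
    estimate of the EID structure, whose residual against X_0 is the
    initial spectral contrast X_S0.  X_L0 holds copies of the EID FBP.
    Returns the state and the EID FBP volume (used for dictionary
    training).
    """
    msm.require_full_rank()
    n_e = len(y_pcd.channels)
    x0 = np.stack(
        [
            ops.bt_interp(fbp_reconstruct(y_pcd.y[e], ops.geom_pcd).data)
            for e in range(n_e)
        ]
    )
    c = decompose(x0, msm, nonneg=False)
    low_res_eid = recompose(c, msm.m_eid)
    xs0 = x0 - low_res_eid[None]
    eid_fbp = fbp_reconstruct(w_eid.y[0], ops.geom_eid).data
    xl0 = np.repeat(eid_fbp[None], n_e, axis=0)
    state = SpectralVolumes(
        xl=xl0, xs=xs0, channels=list(y_pcd.channels), voxel_size=ops.dv_hi
    )
    return state, eid_fbp


def calibrate_params(
    state: SpectralVolumes,
    rhs_norms_l: np.ndarray,
    rhs_norms_s: np.ndarray,
    mu_water: np.ndarray,
    cfg: ReconConfig,
    x_for_noise: np.ndarray | None = None,
) -> CalibratedParams:
    """Analytic estimation of the per-energy regularization weights.

    Noise is measured channel-wise by MAD on tiled volumes; the
    water-normalized, min-normalized ratios delta_e scale both the mu
    parameters (via the right-hand-side norm ratios) and the SVD
    priority weights p_e = 1 / (delta_e mu_water_e).
    """
    x = state.x if x_for_noise is None else x_for_noise
    s = cfg.reg.stride
    sigma = np.array([estimate_noise_mad(tile(xe, s)) for xe in x])
    ratios = sigma / np.asarray(mu_water)
    if np.any(ratios <= 0):
        ratios = np.maximum(ratios, max(ratios.max(), 1e-12) * 1e-6)
    delta = ratios / ratios.min()
    norm_l = np.array([np.linalg.norm(xe) for xe in state.xl])
    norm_s = np.array([np.linalg.norm(xe) for xe in state.xs])
    norm_l = np.maximum(norm_l, 1e-300)
    norm_s = np.maximum(norm_s, 1e-300)
    mu_l = cfg.alpha * delta * rhs_norms_l / norm_l
    mu_s = cfg.alpha * delta * rhs_norms_s / norm_s
    priority = 1.0 / (delta * np.asarray(mu_water))
    return CalibratedParams(
        sigma=sigma, delta=delta, mu_l=mu_l, mu_s=mu_s, priority=priority
    )


def data_fidelity_update(
    state: SpectralVolumes,
    dl: np.ndarray,
    ds: np.ndarray,
    vl: np.ndarray,
    vs: np.ndarray,
    w_eid: ProjectionSet,
    y_pcd: ProjectionSet,
    ops: HybridOperators,
    cfg: ReconConfig,
    params: CalibratedParams,
    n_iters: int | None = None,
) -> SpectralVolumes:
    """One warm-started BiCGSTAB pass over every energy channel."""
    inv_q = 1.0 / wls_weights(w_eid.y[0], cfg.g, cfg.eta)
    n_iters = cfg.bicg_iters if n_iters is None else n_iters
    xl_new = np.empty_like(state.xl)
    xs_new = np.empty_like(state.xs)
    for e in range(len(state.channels)):
        inv_z = 1.0 / wls_weights(y_pcd.y[e], cfg.g, cfg.eta)
        xl_new[e], xs_new[e] = _solve_channel_hybrid(
            ops,
            state.xl[e],
            state.xs[e],
            w_eid.y[0],
            y_pcd.y[e],
            inv_q,
            inv_z,
            cfg.lambda_c,
            params.mu_l[e],
            params.mu_s[e],
            dl[e] - vl[e],
            ds[e] - vs[e],
            n_iters,
        )
    return SpectralVolumes(
        xl=xl_new, xs=xs_new, channels=state.channels, voxel_size=state.voxel_size
    )


def _rhs_norms(ops, w_eid, y_pcd, cfg):
    """Norms of the data-fidelity right-hand sides per energy."""
    inv_q = 1.0 / wls_weights(w_eid.y[0], cfg.g, cfg.eta)
    rt_w = ops.rt(inv_q * w_eid.y[0])
    norms_l, norms_s = [], []
    for e in range(y_pcd.y.shape[0]):
        inv_z = 1.0 / wls_weights(y_pcd.y[e], cfg.g, cfg.eta)
        bt_y = cfg.lambda_c * ops.bt_adjoint(ops.at(inv_z * y_pcd.y[e]))
        norms_l.append(np.linalg.norm(rt_w + bt_y))
        norms_s.append(np.linalg.norm(bt_y))
    return np.asarray(norms_l), np.asarray(norms_s)


def hybrid_reconstruct(
    w_eid: ProjectionSet,
    y_pcd: ProjectionSet,
    msm: MaterialSensitivityMatrix,
    ops: HybridOperators,
    cfg: ReconConfig | None = None,
    return_info: bool = False,
):
    """Full hybrid reconstruction (initialization + split Bregman loop).

    Returns ``(state, concentrations)`` and, optionally, a diagnostics
    dict with per-iteration residual magnitudes and RSKR statistics.
    """
    cfg = cfg or ReconConfig()
    n_e = len(y_pcd.channels)
    state, eid_fbp = component_substitution_init(y_pcd, w_eid, msm, ops)

    # algebraic initialization: pure WLS (mu terms absent), longer solve
    params0 = CalibratedParams(
        sigma=np.zeros(n_e),
        delta=np.ones(n_e),
        mu_l=np.zeros(n_e),
        mu_s=np.zeros(n_e),
        priority=np.ones(n_e),
    )
    state = data_fidelity_update(
        state,
        state.xl,
        state.xs,
        np.zeros_like(state.xl),
        np.zeros_like(state.xs),
        w_eid,
        y_pcd,
        ops,
        cfg,
        params0,
        n_iters=cfg.bicg_init_iters,
    )

    norms_l, norms_s = _rhs_norms(ops, w_eid, y_pcd, cfg)
    params = calibrate_params(state, norms_l, norms_s, msm.mu_water, cfg)

    model = dict_mod.learn_dictionary(
        eid_fbp,
        n_atoms=cfg.reg.n_atoms,
        patch_radius=cfg.reg.patch_radius,
        n_train=cfg.reg.n_train_patches,
        n_iterations=cfg.reg.ksvd_iterations,
        n0=cfg.reg.ksvd_n0,
        stride=cfg.reg.stride,
        seed=cfg.seed,
    )

    vl = np.zeros_like(state.xl)
    vs = np.zeros_like(state.xs)
    priority2 = np.concatenate([params.priority, params.priority])
    info = {"v_norm": [], "rskr_iters": [], "init_state": None}
    if return_info:
        info["init_state"] = SpectralVolumes(
            xl=state.xl.copy(), xs=state.xs.copy(),
            channels=state.channels, voxel_size=state.voxel_size,
        )
    prev_v = None
    for it in range(cfg.n_bregman):
        stack = np.concatenate([state.xl + vl, state.xs + vs], axis=0)
        d_cat, rinfo = rskr(stack, priority2, cfg.reg)
        info["rskr_iters"].append(rinfo["iterations"])
        for i in range(d_cat.shape[0]):
            d_cat[i] = dict_mod.omp_denoise(
                d_cat[i], model, n0_max=cfg.reg.omp_n0, stride=cfg.reg.stride
            )
        dl, ds = d_cat[:n_e], d_cat[n_e:]
        vl = state.xl + vl - dl
        vs = state.xs + vs - ds
        state = data_fidelity_update(
            state, dl, ds, vl, vs, w_eid, y_pcd, ops, cfg, params
        )
        v_mag = float(np.sqrt(np.sum(vl**2) + np.sum(vs**2)))
        info["v_norm"].append(v_mag)
        if prev_v is not None and abs(v_mag - prev_v) <= cfg.bregman_tol * max(
            prev_v, 1e-300
        ):
            break
        prev_v = v_mag

    conc = decompose(state.x, msm, nonneg=True)
    if return_info:
        info["params"] = params
        info["dictionary"] = model
        return state, conc, info
    return state, conc


def pcd_only_reconstruct(
    y_pcd: ProjectionSet,
    msm: MaterialSensitivityMatrix,
    ops: HybridOperators,
    cfg: ReconConfig | None = None,
    return_info: bool = False,
):
    """Control reconstruction using the photon-counting data only.

    Identical split Bregman structure, but X is reconstructed directly
    (no EID fidelity term) and the dictionary is trained on the
    inverse-variance weighted average of the initialized channels.
    """
    cfg = cfg or ReconConfig()
    n_e = len(y_pcd.channels)
    x = np.stack(
        [
            ops.bt_interp(fbp_reconstruct(y_pcd.y[e], ops.geom_pcd).data)
            for e in range(n_e)
        ]
    )
    # algebraic initialization, pure WLS
    for e in range(n_e):
        inv_z = 1.0 / wls_weights(y_pcd.y[e], cfg.g, cfg.eta)
        x[e] = _solve_channel_pcd(
            ops, x[e], y_pcd.y[e], inv_z, cfg.lambda_c, 0.0, None, cfg.bicg_init_iters
        )

    s = cfg.reg.stride
    sigma = np.array([estimate_noise_mad(tile(xe, s)) for xe in x])
    ratios = np.maximum(sigma / np.asarray(msm.mu_water), 1e-300)
    delta = ratios / ratios.min()
    norms = []
    for e in range(n_e):
        inv_z = 1.0 / wls_weights(y_pcd.y[e], cfg.g, cfg.eta)
        norms.append(
            np.linalg.norm(cfg.lambda_c * ops.bt_adjoint(ops.at(inv_z * y_pcd.y[e])))
        )
    mu = cfg.alpha * delta * np.asarray(norms) / np.maximum(
        np.array([np.linalg.norm(xe) for xe in x]), 1e-300
    )
    priority = 1.0 / (delta * np.asarray(msm.mu_water))

    inv_var = 1.0 / np.maximum(sigma, 1e-300) ** 2
    weights = inv_var / inv_var.sum()
    train_vol = np.tensordot(weights, x, axes=(0, 0))
    model = dict_mod.learn_dictionary(
        train_vol,
        n_atoms=cfg.reg.n_atoms,
        patch_radius=cfg.reg.patch_radius,
        n_train=cfg.reg.n_train_patches,
        n_iterations=cfg.reg.ksvd_iterations,
        n0=cfg.reg.ksvd_n0,
        stride=cfg.reg.stride,
        seed=cfg.seed,
    )

    v = np.zeros_like(x)
    info = {"v_norm": [], "rskr_iters": [], "train_weights": weights}
    prev_v = None
    for it in range(cfg.n_bregman):
        d, rinfo = rskr(x + v, priority, cfg.reg)
        info["rskr_iters"].append(rinfo["iterations"])
        for i in range(n_e):
            d[i] = dict_mod.omp_denoise(
                d[i], model, n0_max=cfg.reg.omp_n0, stride=cfg.reg.stride
            )
        v = x + v - d
        for e in range(n_e):
            inv_z = 1.0 / wls_weights(y_pcd.y[e], cfg.g, cfg.eta)
            x[e] = _solve_channel_pcd(
                ops,
                x[e],
                y_pcd.y[e],
                inv_z,
                cfg.lambda_c,
                mu[e],
                d[e] - v[e],
                cfg.bicg_iters,
            )
        v_mag = float(np.linalg.norm(v))
        info["v_norm"].append(v_mag)
        if prev_v is not None and abs(v_mag - prev_v) <= cfg.bregman_tol * max(
            prev_v, 1e-300
        ):
            break
        prev_v = v_mag

    state = SpectralVolumes(
        xl=np.zeros_like(x), xs=x, channels=list(y_pcd.channels), voxel_size=ops.dv_hi
    )
    conc = decompose(x, msm, nonneg=True)
    if return_info:
        info["params"] = CalibratedParams(
            sigma=sigma, delta=delta, mu_l=np.zeros(n_e), mu_s=mu, priority=priority
        )
        return state, conc, info
    return state, conc
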