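"""Shared fixtures.

The desk-scale end-to-end experiment (full hybrid and PCD-only
reconstructions of the 3D phantom) is expensive, so it runs once per
session and is shared by every test that scores it.
"""

from __future__ import annotations

import numpy as np
import pytest

from hybridct.workbench import ExperimentConfig, make_fixture


def desk_config(seed: int = 11) -> ExperimentConfig:
    """The reduced-scale 3D experiment used for end-to-end scoring.

    One fifth of the full phantom extent with thin disks, reduced
    dictionary size and solver iteration counts; voxel sizes, PSFs,
    fluxes, energy thresholds and all spectral conditions are the
    full-scale ones.
    """
    return ExperimentConfig(
        scale=0.2,
        seed=seed,
        phantom={"disk_height": 4.4, "sphere_diameters": (4.0, 2.5), "n_bars": 2},
        bf_radius=4,
        patch_radius=2,
        n_atoms=128,
        ksvd_iterations=8,
        ksvd_n0=12,
        n_train_patches=20_000,
        bicg_init_iters=20,
        bicg_iters=12,
        n_bregman=6,
    )


@pytest.fixture(scope="session")
def desk_experiment():
    """Fixture + hybrid + PCD-only reconstructions at desk scale."""
    from hybridct import hybrid_reconstruct, pcd_only_reconstruct

    cfg = desk_config()
    fx = make_fixture(cfg)
    rcfg = cfg.recon_config()
    state, conc, info = hybrid_reconstruct(
        fx.eid, fx.pcd, fx.msm, fx.ops, rcfg, return_info=True
    )
    state_p, conc_p, info_p = pcd_only_reconstruct(
        fx.pcd, fx.msm, fx.ops, rcfg, return_info=True
    )
    return {
        "cfg": cfg,
        "fx": fx,
        "hybrid": state,
        "hybrid_conc": conc,
        "hybrid_info": info,
        "pcd": state_p,
        "pcd_conc": conc_p,
        "pcd_info": info_p,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
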