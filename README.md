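# hybridct

Joint iterative reconstruction of hybrid spectral micro-CT data: one
high-resolution, low-noise **energy-integrating** (EID) acquisition fused
with five lower-resolution, noisier **photon-counting** (PCD) acquisitions
taken at energy thresholds of 26/34/37/39/45 keV. The package targets
preclinical K-edge imaging — separating iodine (K edge 33.2 keV) and
barium (37.4 keV) contrast agents whose spectral separation is on the
order of the detector's energy resolution — and ships the digital
spectral phantom, projection simulator and evaluation metrics needed to
exercise the method end to end with no external data.

## The model

The log projections are modeled as

```
w   = R x_L                      (EID chain)
y_e = A B (x_L,e + x_S,e)        (PCD chain, threshold e)
```

with `R`, `A` the chain projection operators and `B` a Gaussian
blur/downsampling operator (sigma_r = 0.078 mm) coupling the 88 um EID
grid to the 127 um PCD grid. `X_L` holds redundant copies of the EID
image, `X_S` the spectral contrast; their sum is the high-resolution
spectral estimate. Reconstruction minimizes the weighted least-squares
data fidelity of both chains subject to a low-spectral-rank and joint
gradient-sparsity constraint, solved with the split Bregman method:

1. **Component substitution** initializes `X_S` by material-decomposing
   the upsampled PCD reconstructions (basis: photoelectric, Compton,
   iodine, barium) and subtracting the EID-recomposed estimate.
2. **RSKR** (rank-sparse kernel regression) filters the prioritized
   singular vectors of `[X_L + V_L, X_S + V_S]` with joint bilateral
   filtration, averaging a tiled (stride 3) and untiled pass, with
   per-vector strengths `h_i = h0 (e_1 / e_i)^gamma`.
3. **Dictionary sparse coding** (K-SVD + orthogonal matching pursuit)
   regularizes every channel against a patch dictionary trained on the
   EID reconstruction, preserving patch means exactly.
4. **Data fidelity updates** re-solve the coupled per-energy normal
   equations with warm-started BiCGSTAB.

A PCD-only control runs the identical loop without the EID fidelity
term; comparing the two isolates what the EID data buys. Details and
parameter rationale: [docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from hybridct import (ExperimentConfig, make_fixture,
                      hybrid_reconstruct, pcd_only_reconstruct)

cfg = ExperimentConfig(scale=0.2, single_slice=True, seed=3,
                       bf_radius=4, patch_radius=2, n_atoms=96,
                       ksvd_iterations=6, ksvd_n0=12, n_train_patches=8000,
                       bicg_init_iters=20, bicg_iters=12, n_bregman=4)
fx = make_fixture(cfg)                      # phantom + both sinogram sets
state, conc = hybrid_reconstruct(fx.eid, fx.pcd, fx.msm, fx.ops,
                                 cfg.recon_config())
ctrl, _ = pcd_only_reconstruct(fx.pcd, fx.msm, fx.ops, cfg.recon_config())

for ci, ch in enumerate(state.channels):
    muw = fx.msm.mu_water[ci]
    masks = [fx.layout.vial_mask_2d(v) for v in fx.layout.vials]
    h = np.mean([state.x[ci][m].std() for m in masks]) * 1000 / muw
    p = np.mean([ctrl.x[ci][m].std() for m in masks]) * 1000 / muw
    print(f"{ch:>5} keV vial noise SD: hybrid {h:5.0f} HU   PCD-only {p:5.0f} HU")
```

prints (seed 3):

```
 26.0 keV vial noise SD: hybrid   133 HU   PCD-only   156 HU
 34.0 keV vial noise SD: hybrid    96 HU   PCD-only    97 HU
 37.0 keV vial noise SD: hybrid    97 HU   PCD-only   112 HU
 39.0 keV vial noise SD: hybrid   107 HU   PCD-only   135 HU
 45.0 keV vial noise SD: hybrid   125 HU   PCD-only   167 HU
```

i.e. fusing the EID data cuts the calibration-vial noise in every
energy channel of the same PCD data. `conc` holds the non-negative
material decomposition (mg/ml for iodine/barium; pure water decomposes
to PE = CS = 1 by construction).

A thin CLI wraps the same pipeline: `hybridct fixture|simulate|
preprocess|reconstruct|evaluate --config cfg.yaml --seed N --out DIR`.

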