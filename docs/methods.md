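# Methods

`hybridct` implements joint iterative reconstruction of hybrid spectral
micro-CT data: one high-resolution, low-noise energy-integrating (EID)
projection set and five lower-resolution, noisier photon-counting (PCD)
projection sets acquired at energy thresholds of 26/34/37/39/45 keV.
This note records the model, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Forward model and data fidelity

Log-transformed, gain-corrected line integrals are modeled linearly:
`w = R x_L` for the EID chain and `y_e = A B (x_L,e + x_S,e)` for each
PCD threshold, where `R` and `A` are the chain projection operators,
`B` is a normalized Gaussian blur/downsampling operator that maps the
EID-resolution grid (88 um voxels) onto the PCD grid (127 um voxels),
`X_L` holds redundant copies of the EID image and `X_S` the spectral
contrast contributed by the PCD channels. The coupling width is
`sigma_r = sqrt(FWHM_PCD^2 - FWHM_EID^2) / (2 sqrt(2 ln 2)) = 0.078 mm`
for the measured chain PSFs (0.254 / 0.176 mm FWHM).

Both fidelity terms are weighted least squares with per-ray variance
estimates `q_i^2 = g exp(w_i / eta)` (defaults `g = 1`, `eta = 3`); the
conservative `eta` leaves the algebraic solution essentially unweighted
and instead modulates the effective regularization strength with
attenuation.

Design choices that were genuinely open:

- **Units and the `c` scale of `B`.** All volumes are linear
  attenuation in mm^-1 and all sinograms physical log line integrals,
  so the value-preserving choice `c = 1` is used inside the
  reconstruction; the voxel-length-ratio scaling needed by per-voxel
  unit conventions is available as an explicit argument and is
  exercised by the tests.
- **Adjoint of `B`.** The upsampling operator used to initialize `X_0`
  is the value-preserving normalized-kernel interpolation ("logical
  transpose"). Inside the solver, however, the exact matrix transpose
  of `B` is used, so the coupled per-energy equations are the true
  normal equations of the weighted least-squares objective. The two
  differ by normalization only; using the exact adjoint removes a
  fixed-point bias at no cost.
- **Projectors.** Matched Joseph-style interpolating ray tracing for
  forward and back projection, built as an exact transpose pair
  (adjoint mismatch at machine precision). Filtered backprojection
  uses a discrete Ram-Lak kernel (optional Hann apodization) and
  pixel-driven backprojection; fan-beam weighting follows the standard
  flat-detector full-scan formulas. A circular cone-beam trajectory is
  represented in desk mode as a stack of identical fan-beam slices
  ("fan3d"); at the small cone angles of the scaled experiments the
  difference from a full cone-beam model is negligible relative to the
  effects under study.
- **Algebraic initialization** solves the fidelity-only system (no mu
  terms) with warm-started BiCGSTAB; the limited iteration count is the
  only (implicit) regularization at that stage.

## Split Bregman loop

Each global iteration applies, in order: rank-sparse kernel regression
(RSKR) on the prioritized concatenation `[X_L + V_L, X_S + V_S]`,
dictionary-based sparse coding of every regularized column,
add-residual-back updates `V <- X + V - D`, and per-energy BiCGSTAB
data-fidelity solves with the penalty weights `mu_L,e`, `mu_S,e`. One
(D, V) pair is tracked after both regularizers. The loop runs at most
six iterations and stops early when the residual magnitude changes by
less than 1%.

Calibration is analytic: channel noise `sigma_e` is the MAD of the
all-high-pass Haar band measured on *tiled* volumes; water-normalized,
min-normalized ratios `delta_e` scale both the penalty weights (via
the right-hand-side norm ratios and the scale factor `alpha = 0.01`)
and the SVD priority weights `p_e = 1 / (delta_e mu_water,e)`.

### RSKR

The prioritized column matrix is decomposed by reduced SVD; the left
singular vectors are filtered by joint bilateral filtration (BF) inside
an internal Bregman loop (at most six iterations, 1% residual-change
tolerance). Per-vector filter strengths follow the singular-value
ratio rule `h_i = h0 (e_1 / e_i)^gamma` with `h0 = 1.5`, `gamma = 0.5`,
so weak singular vectors are regressed toward the structure of strong
ones; the same `h_i` balances the analytic data-fidelity update
`u_i = (u_{0,i} + h_i (l_i - f_i)) / (1 + h_i)`. The `h_i` are fixed
from the initial decomposition for the whole internal loop. Each BF
pass is the arithmetic mean of an untiled and a tiled (stride 3)
filtration of the same input, with the noise level re-measured by MAD
immediately before each pass; tiling converts low-frequency correlated
noise (introduced by upsampling the PCD data) into high-frequency noise
that a radius-6 spherical domain can remove. The range kernel uses the
delta resampling kernel and is jointly computed across all channels.
Vectors with numerically zero singular values are dropped from
filtering and carry no data. The reprojection variant of the
recomposition (projecting the input onto the filtered subspace instead
of recomposing with the original singular values) is implemented behind
`RegularizerConfig.use_reprojection` and off by default, since it
trades spectral bias for robustness.

### Dictionary learning and OMP

A K-SVD dictionary of unit-norm, zero-mean radial-patch atoms is
trained once per reconstruction: on the EID filtered backprojection for
the hybrid problem, and on the inverse-variance weighted average of the
initialized channels for the PCD-only control. Training draws patches
whose variance exceeds the (tiling-robust) MAD noise level; under-used
or near-duplicate atoms are replaced by the worst-coded patches.
Sparse coding uses batch orthogonal matching pursuit with batched
normal-equation updates; ties in the correlation maximum resolve to the
lowest atom index, and atoms already in a patch's support are excluded
from re-selection to guard against round-off. Coding stops per patch
at `n0 = 5` atoms or at the noise-calibrated residual level
`||r||^2 <= n_v MAD(tile(vol, 3))^2`. Patch means are subtracted
before coding and restored afterwards; the volume is edge-padded by the
patch radius so that every voxel receives the full overlapping-patch
coverage, which carries the per-patch mean preservation over to the
volume mean (verified to 1e-4 relative).

Full-scale defaults follow the published configuration (1024 atoms,
radius-4 radial patches, 25 K-SVD iterations, 500k training patches,
training `n0 = 48`); the desk-scale experiments reduce these (128
atoms, radius 2, 8 iterations, 20k patches) to keep end-to-end runs in
minutes on one CPU.

## Spectral model and simulator

Attenuation data are generated by an in-source model: exact
Klein-Nishina Compton cross sections plus a photoelectric(+coherent)
`1/E^3` component anchored per element to tabulated reference values,
with K-shell jump ratios at the printed edge energies (iodine 33.2 keV,
barium 37.4 keV). Validation against standard water values stays
within ~3.5% over 15-80 keV; mid-Z elements are good to ~10-15%, which
is adequate for effective-attenuation modeling at these energies. The
tube model is thick-target bremsstrahlung in Kramers' intensity form
(photon fluence proportional to kVp - E) with tungsten K lines above
69.5 keV.

The chain responses are calibrated against the documented behavior of
the system being modeled, in the same spirit in which that system's
spectral model was itself tuned against measured noise and sensitivity
conditioning. Specifically, each chain carries an inherent-filtration
aluminum equivalent (anode self-filtration, tube port, detector cover):
1.0 mm on the EID chain (on top of the stated 0.7 mm Al + 3 mm PMMA;
Gd2O2S scintillator absorption at 34 mg/cm^2 areal density with energy
weighting) and 1.2 mm on the PCD chain (on top of the 0.25 mm Be
window; 1 mm CdTe quantum efficiency). With these fixed choices the
model reproduces, at the stated photon budgets of 5e4 (EID) and 4.2e3
(PCD) photons per line integral, FBP water-noise levels of ~80 HU (EID,
88 um voxels) and ~235 HU to ~415 HU (PCD thresholds 26 to 45 keV,
127 um voxels), and material-sensitivity condition numbers of 39.4
(ideal rectangular thresholds) and 107 (Gaussian energy spread,
sigma = 3.25 keV) against the reference values 40 and 100. Condition
numbers including the EID channel as a sixth row are also computed
(38.0 rect / 68.2 with energy spread); the five-threshold form matches
the reference conditioning and is the one reported.

Projection synthesis integrates the spectral transmission over a 1 keV
energy grid (10-80 keV, trapezoidal quadrature). Material density maps
are blurred with the chain PSF and resampled onto the chain's voxel
grid before projection; counts are Poisson-distributed per detector
cell, with three sub-rays per cell modeling the aperture integration.
Counts below one are clamped to one before the log transform and
counted as a warning. Energy channels are independent thresholds
(counts above each threshold), not bin-differenced data.

The PE/CS basis functions (photoelectric `1/E^3` and Klein-Nishina
shapes) are projected onto the span of the effective water and calcium
sensitivities and rescaled so pure water decomposes to PE = CS = 1;
because the in-source attenuation model is itself built from these two
shapes, the projection change is numerically zero (the reference
implementation reports <3%). Non-negative material decomposition is
solved exactly by exhaustive active-set search over the 2^4 sign
patterns, which is cheap at four basis materials and avoids the
approximations of iterative projection methods.

## Phantom and scaling

The digital phantom is a 34 mm water cylinder with three disks (iodine
15, calcium 75, barium 15 mg/ml), bar patterns at eight voxel-defined
frequencies (half-periods of 1-8 voxels, 0.71-5.68 lp/mm at 88 um),
a sphere grid (diameters 2.0-0.5 mm, concentration fractions
1.0/0.66/0.33/0.20), and four calibration vials (iodine, calcium,
barium at half the disk maximum, plus water) spanning all disks.
Voxelization is center-point sampling; band limiting comes from the
chain PSFs downstream. All measurement regions (bars, gaps, vials,
lesion ROIs) derive from the same layout object, never from the data.

Scaled experiments shrink the phantom extent and projection counts
proportionally while keeping voxel sizes, their ratio, the PSFs, the
fluxes and the spectral model fixed, so voxel-defined quantities
(notably the 2.84 lp/mm bars, two voxels per half-period) are scale
invariant. The end-to-end desk experiment uses scale 0.2 with thinned
disks (0.88 mm), two-bar groups, sphere diameters 0.8/0.5 mm, 72/80
projections and reduced solver budgets (BiCGSTAB 20 init / 12 per
iteration); these problem sizes keep a full hybrid + control pair
around ten minutes on one CPU. Because the scaled water path is
shorter, the scaled data are somewhat noisier per ray than at full
scale (fewer views dominate the transmission gain), i.e. the desk
regime is slightly harder than the full-scale one, not easier.

What the synthetic experiments do not show: detector physics beyond
Poisson counting and a Gaussian PSF (no charge sharing, pulse pile-up,
K-escape, scatter, or focal-spot structure), geometric miscalibration
or motion between chains (the simulator guarantees co-registered
geometry, so the registration machinery a physical system needs is out
of scope), and absolute attenuation accuracy beyond the ~10% level of
the parametric tables. Beam hardening *is* present in the simulated
data (the reconstruction model is log-linear), so vial biases include a
genuine spectral-artifact component.

## Evaluation conventions

Hounsfield conversion uses the per-channel effective water attenuation.
Modulation transfer is computed on water-subtracted bar/gap means with
negative values clipped to zero; the full phantom yields 120
measurements (8 frequencies x 3 disks x 5 thresholds) to which a
single-parameter Gaussian MTF `exp(-l^2 / (2 sigma^2))` is fitted
(`sigma` shares the units of the frequency axis, lp/mm). The
detectability index uses a non-prewhitening observer with the unitary
DFT convention; absolute values depend on that convention, so only
hybrid / PCD-only ratios are compared. Lesion ROIs are cubes centered
on the known sphere positions (side 32 voxels at full scale, 8 at desk
scale, non-overlapping by construction).

## Known limitations

- The detector-cell aperture is modeled in the simulator (sub-ray
  averaging) but not in the reconstruction projectors, which are
  interpolating ray tracers; footprint projectors would slightly soften
  the modeled system matrix.
- The MAD estimator assumes approximately white noise within each
  channel after tiling; strongly structured residuals (e.g. streaks
  from photon starvation) bias it upward, which errs on the side of
  stronger regularization.
- BiCGSTAB runs a fixed iteration budget rather than to a residual
  tolerance; the budget is part of the configuration and the reported
  results state the budgets used.
- The PCD-only control shares every component with the hybrid path
  except the EID fidelity term and the dictionary training volume, so
  comparisons isolate the contribution of the EID data rather than
  implementation differences.
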