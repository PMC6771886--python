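# Methods

`cestpvc` quantifies amide proton transfer (APT) effects from CEST MRI
z-spectra with an explicit correction for cerebrospinal-fluid (CSF) partial
volume. This note records the models, the numerical choices, and the design
decisions that were genuinely open, together with what the synthetic tests do
and do not demonstrate.

## Forward model

Each voxel is described by exchanging magnetization pools. Pool `i` has a
relative concentration `m0_i` (water carries the absolute scale), exchange
rate `kex_i` (pool to water, s⁻¹), relaxation times `T1_i`, `T2_i`, and a
chemical shift `dw_i` in ppm from water. Under continuous-wave (CW)
irradiation at amplitude `B1` and offset `w` the stacked transverse and
longitudinal components obey the linear Bloch-McConnell system
`dM/dt = A M + b`, with:

* relaxation `-1/T2` (x, y) and `-1/T1` (z) on the block diagonals;
* precession at `2*pi*larmor*(w - dw_i - b0)` rad/s (ppm times the Larmor
  frequency in MHz), where `b0` is the voxel's water-frequency shift;
* nutation at `w1 = gamma*B1`;
* exchange with detailed balance: pool-to-water at `kex_i`, water-to-pool at
  `kex_i * m0_i` (concentrations relative to water), so thermal equilibrium
  is an exact fixed point of the free dynamics.

The spectrum is the water z-component after the saturation time `t_sat`,
starting from equilibrium, normalized by the water equilibrium signal:
`M(t) = M_ss + V exp(L t) V^-1 (M(0) - M_ss)` with `(L, V)` the
eigendecomposition of `A` and `M_ss = -A^-1 b`. A Padé matrix-exponential
fallback on the affine-augmented system covers near-defective generators. At
`B1 = 0` equilibrium is stationary and the signal is identically 1. Because
solute concentrations are relative, the normalized spectrum is exactly
invariant to the water scale; the fitted water `m0` is then a pure scale
parameter and cannot leak into concentration estimates.

Pulsed saturation trains are mapped to CW through the power-equivalent
amplitude: the pulse area fixes the peak (`integral gamma B1 dt = flip`) and
the CW value is the RMS of `B1(t)` over the full pulse-plus-gap cycle
(optionally over the pulse alone; both readings of "average power" are
exposed because the acquisition description does not disambiguate them). A
184-degree Gaussian pulse of 20 ms with a 20 ms gap and 1% edge truncation
gives 0.557 uT, matching the protocol's nominal 0.55 uT; 50 such cycles give
the default `t_sat = 2.0 s`. The default Larmor frequency is 127.74 MHz
(3 T). Positive ppm is downfield; amide sits at +3.5 ppm. The semisolid pool
uses the same Lorentzian-type Bloch formalism as the other pools (`dw = 0`,
`T2 = 10 us`); no super-Lorentzian lineshape is implemented.

## Tissue/CSF mixture (partial-volume correction)

A voxel with tissue fraction `p` (the tissue partial-volume estimate, PVE,
supplied by an upstream GM+WM segmentation) is modelled as

    S_total(w) = (1 - p) * S_CSF(w) + p * S_tissue(w)

with `S_tissue` from the 4-pool tissue model (water, amide, semisolid MT,
NOE) and `S_CSF` from a 1-pool CSF model. Both compartments share the
voxel's `b0`, and both spectra are normalized by the combined unsaturated
signal `s0 = (1-p)*m0_CSF + p*m0_water`, so the weighted sum holds at
machine precision exactly as written. The CSF concentration is never free:
it is pinned to `ratio * m0_water` with `ratio = 0.53` by default, because a
free CSF scale lets the tissue compartment alone absorb the whole spectrum
and the mixture degenerates. The ratio can be re-estimated from unsaturated
images by a two-regressor least squares of `S0` on the tissue and CSF PVE
maps (with a voxel bootstrap for its uncertainty); this transparent
estimator is our choice — the upstream analysis that produced 0.53 did not
specify its procedure.

CSF pool defaults: `T1 = 4.3 s` and an **effective** `T2 = 0.2 s`. The
intrinsic CSF T2 at 3 T approaches 2 s, but a CW pool with intrinsic T2
comparable to `t_sat` retains coherent Rabi oscillations, so its signal
oscillates in `b0` with a period of roughly 0.001 ppm — a needle-shaped,
physically spurious likelihood that no per-voxel B0 fit can traverse, and
structure that real (dephasing-broadened, pulse-saturated) CSF spectra do
not show. The effective T2 represents the observable linewidth; it is a
config value, not a certified constant.

## Voxelwise fitting

The estimator is maximum a posteriori (MAP) under independent Gaussian
priors on transformed parameters — log scale for concentrations and exchange
rates (guaranteeing positivity), linear for relaxation times and shifts —
with Gaussian observation noise. This is the same statistical model as the
variational-Bayes routines used for this analysis class; the contract here
is parameter recovery, not bit-identity with any particular solver.
Implementation: penalized Levenberg-Marquardt in which prior terms enter as
extra residual rows; the Laplace posterior covariance is the inverse
Gauss-Newton Hessian at the mode (data rows scaled by `1/sigma`, prior
rows by `1/sd`); posterior sds of log-scale parameters are mapped to the
natural scale by the delta method.

Three model tags exist: `four_pool` (tissue only), `pvc` (mixture; the
voxel's PVE enters as a fixed constant, never fitted), and `csf_only`.
Voxels with tissue PVE below 0.50 are deemed non-interpretable for tissue
models: they receive the CSF-only fit and are excluded from all APT maps
and statistics (PVE exactly 0.50 gets the tissue model). Voxels are fitted
independently — no spatial regularization — so results are invariant to
voxel order.

Free parameters by default: water `m0`, `T1`, `T2`; solute `m0`, `kex`,
`T2` (solute `T1` fixed); and always the per-voxel `b0`. Defaults are
editable per fit.

**Noise.** The noise sd is re-estimated between Levenberg-Marquardt passes
from successive differences of the data residuals along the offset axis,
with the largest quarter of the squared differences trimmed (consistency
factor 0.3685 restores unbiasedness for Gaussian noise). Two properties
motivated this over the usual residual-variance update: (i) smooth model
misfit — an uncorrected CSF contribution under the 4-pool model — cancels in
adjacent differences, so misfit is not booked as noise; a residual-RMS
update inflates sigma precisely where the model is most misspecified and
lets the priors swamp the data there, which destroys the monotone dilution
behaviour the uncorrected model should show. (ii) The trim stops a sharp
localized misfit line (a couple of offsets wide) from masquerading as noise,
and is statistically much more efficient than a median-based rule (severe
underestimates of sigma, which make the fit chase noise, become ~10x rarer).

**Initialization.** Parameters start at the prior means except `b0`, which
starts at the parabola-interpolated minimum of the measured z-spectrum near
water — the standard direct-saturation landmark. A zero start can leave the
optimizer stranded with the narrow CSF line misplaced against the data.
Optimizer tolerances: 1e-8 on the objective, 1e-6 on the transformed step;
at most 500 iterations; non-convergence is flagged, never silently dropped.

**Priors.** The default table uses physiologically informative widths:
log-sd 0.35 for amide and NOE concentrations, 0.3 for the semisolid
concentration, 0.2 for exchange rates; water `T1 = 1.3 +/- 0.3 s`,
`T2 = 55 +/- 20 ms`; `b0 = 0 +/- 0.3 ppm`. These widths are load-bearing:
measured on synthetic voxels at the default protocol and 1% noise, the
profile likelihood of the amide concentration alone has a log-sd near 0.9,
because localized changes in the 3.5 ppm dip can be absorbed cheaply by
water, MT and NOE parameters. With weak (log-sd 0.7) priors the posterior
develops a spurious high-amide mode that wins for roughly one noise draw in
ten and inflates the mean amide estimate by ~17%; informative concentration
priors are what make single-voxel multi-pool fitting identifiable at
clinical SNR, which is the premise of Bayesian z-spectrum analysis in
general. The values are plain config data and carry no claim of being the
original study's exact table.

## APTR* quantification

APTR* is the model-based APT metric: re-simulate the fitted tissue system
with and without the amide pool, evaluate both at +3.5 ppm, and take the
difference normalized by the fitted water signal. For a `pvc` fit only the
tissue compartment enters, so the measure is undiluted by CSF. Evaluation
is at the amide resonance of the B0-corrected frame by default (the fitted
shift defines the voxel's frequency axis); evaluation at the nominal
acquisition offset is available. `S0` is the fitted water equilibrium
signal, making the metric self-contained in fitted quantities and exactly
invariant to the overall signal scale. A fitted amide concentration of zero
yields exactly zero.

Analysis masks threshold the tissue PVE map: whole slice `[0.50, 1.00]`,
low-PVE `[0.50, 0.75)`, high-PVE `[0.75, 1.00]`. The 0.75 boundary belongs
to both printed ranges; it is assigned to the high band so the two bands
partition the whole-slice mask.

## Robustness statistics

Coefficient of variation (CoV) is `100 * sample sd / mean` with the (n-1)
divisor throughout (the divisor was unstated upstream; sample sd is our
choice). Between-timepoint repeatability is each subject's CoV of
per-timepoint ROI means, averaged over subjects (mean and sd reported);
between-subject repeatability is the CoV across per-subject means (ROI-mean
values, not voxelwise — also a choice where the source is silent). Spatial
variability is the CoV of voxel values within an ROI. Ischemic-core
contrast-to-noise is `(mean_core - mean_contralateral) / sd_contralateral`.
The CSF-fraction profile bins CSF PVE into ten equal ranges over [0, 0.5]
(last edge inclusive) and reports the per-bin APTR* means and the CoV of
the non-empty bin means. All statistics are invariant to voxel order and to
scaling, where applicable. Group significance testing (ANOVA etc.) is out
of scope; the tidy CSV output is designed so users can run it externally.

## Digital stroke phantom

The phantom is the toolkit's test surface. Defaults: a 16x16x1 grid whose
tissue PVE rises column by column from a CSF band (0, 0, 0.2, 0.4, 0.6,
0.8, then 1.0), `tissue_pve + csf_pve = 1` everywhere; a 4x4 ischemic-core
box in pure tissue with the amide concentration multiplied by 0.7 (a 30%
reduction, the magnitude seen in ischemia) and a contralateral box mirrored
across the midline, also in clean tissue; a smooth polynomial B0 field with
|b0| up to ~0.05 ppm; Gaussian noise in the signal domain with sd 1% of the
tissue water signal (clinical-SNR scale; magnitude-Rician behaviour is
ignored as standard at this SNR). Every voxel's clean spectrum is built by
the same mixture forward model the fitting stage uses, on the absolute
signal scale, so ground-truth round trips are exact at zero noise. Phantom
and fit share one parameter registry; identical specs and seeds give
bit-identical data. A PVE-ramp variant (tissue fraction 0.5 to 1.0 across
columns, constant tissue, no lesion, zero noise) isolates the CSF dilution
artifact.

What the phantom does *not* emulate: anatomy, coil profiles, EPI
distortion, motion, segmentation errors in the PVE maps, GM/WM contrast,
spatial noise correlation, and magnitude (Rician) noise. Passing tests
therefore demonstrate the correctness and the internal robustness ordering
of the two quantification models under the stated generative assumptions,
not clinical performance.

## Problem sizes and observed behaviour

The test suite and the acceptance script use: 20 random 2-4 pool systems at
33 offsets for the propagator oracle (the oracle integrates all offsets as
one stacked ODE; solute T2 there stays above 1 ms because a 10 us T2 pool
saturated for 2 s at a 300 ppm offset — some 76,000 precession periods — is
beyond any adaptive time-stepping integrator, and that stiff corner is
checked against the independent Padé matrix exponential instead); 100
voxels for the amide recovery study; a 6-step ramp; and ROI-restricted fits
(core plus contralateral, 32 voxels per model) on the default stroke
phantom. A full-slice 16x16 fit takes a few minutes per model on one CPU;
an ROI fit runs in seconds.

On these conditions the pipeline shows: exact mixture linearity; amide
recovery bias ~4-7% with ~95-99% coverage of +/-2 posterior sd at 1% noise;
B0 recovery to ~1e-12 ppm on noiseless data with APTR* insensitive to a 0.1
ppm shift; a monotone 4-pool dilution of ~43% across the ramp removed to
numerical precision by the correction; and equal core CNR for both models
(the default ROIs lie in pure tissue, where the models provably coincide).

## Known limitations

* Per-voxel amide contrast at 1% noise is information-limited: the 30%
  lesion reduction (0.36 in log units) is far below the ~0.9 log-sd of the
  single-voxel amide likelihood, so voxelwise lesion classification from
  amide estimates is impossible in principle at this SNR, and prior
  shrinkage compresses the fitted ROI contrast (to roughly -5% at the
  defaults). ROI averaging restores the effect's sign; with the default
  16-voxel ROIs the stroke CNR is negative in expectation but its sign can
  flip for individual noise seeds.
* The MAP estimate of a log-scale concentration is its posterior median,
  not mean; averaging natural-scale estimates across voxels therefore
  carries a positive Jensen-type bias of order `exp(sd_log^2/2) - 1`
  (about 4-7% here).
* The CW approximation ignores intra-train relaxation dynamics; the pulsed
  train is represented only through its power-equivalent amplitude.
* The noise sd estimator assumes the true spectrum varies smoothly between
  adjacent offsets; protocols with very sparse or highly irregular sampling
  would need the gap threshold (1 ppm) revisited.
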