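# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `vfadesign`. Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal model and noise conventions

The SPGR steady-state signal is `S = M0 (1 − E1) sin α / (1 − E1 cos α)`
with `E1 = exp(−TR/T1)`; `M0` lumps proton density, T2* decay at the echo
time and receive sensitivity into one positive constant. Angles cross every
public interface in degrees; all flip-angle derivatives are per radian,
computed analytically (`dS/dM0 = S/M0` exactly; the α-derivative vanishes at
the Ernst angle `arccos E1`). Noise on magnitude SPGR images is modeled as
additive Gaussian — no Rician correction — because the likelihood
underlying the Fisher matrix is Gaussian and the operating SNRs (≥ 12) keep
magnitude noise effectively Gaussian.

SNR values are anchored to explicit operating points, because an "SNR"
without a reference signal is meaningless for design work:

* SPGR: `σ_SPGR = S(2° true, TR 4.1 ms, T1 800 ms, M0 5000) / SNR`
  (= 156.0/SNR). The reference uses the *true* flip angle; whether the
  reference should instead be the nominal angle at some B1+ is exposed
  through `sigma_from_snr`'s parameters.
* B1+ mapping: per-channel complex noise SD equals
  `|S_slice(65° true)| / SNR`, so the magnitude SNR at a true flip of 65°
  equals the requested value; the same absolute SD applies at both flip
  angles of the pair.

The B1+ factor SD `σ_B1` is an absolute SD of the (order-one) factor: a
"4.6 %" map uncertainty enters as 0.046.

## Cramér–Rao bound and min-max flip-angle search

For θ = (M0, T1) the 2×2 Fisher matrix sums, over measurements,
`(1/σ_i²)` times outer products of `(∂S/∂M0, ∂S/∂T1)` evaluated at the true
flip `B1+·α_nominal`. The total per-measurement variance is

    σ_i² = σ_SPGR² + ( ∂S_i/∂α_true · α_i,nominal[rad] · σ_B1 )²,

the second term being the first-order image-domain effect of a B1+ factor
error of SD σ_B1 at measurement i. Two modeling consequences are
deliberate and documented:

* **Diagonality.** B1+ noise is treated as independent across measurements
  (a diagonal total covariance). A real B1+ map error is *shared* by all
  flip angles of a voxel and is not representable in this scalar-sum form;
  the Monte-Carlo validation therefore also draws B1+ perturbations
  independently per measurement, so that it validates exactly the model the
  bound is computed from. Correlated map error is a known limitation.
* **Inversion.** The 2×2 inverse is closed-form. Designs whose Fisher
  matrix is singular or has spectral condition number above 1e12 (one
  distinct flip angle, or α → 0) report infinite T1 variance instead of
  raising, so exhaustive searches can sweep degenerate corners safely.

The design criterion is the worst-case `COV = 100·sqrt([F⁻¹]_T1,T1)/T1`
over a (T1, B1+) grid. Defaults target the liver at 3T: T1 700–1200 ms in
100 ms steps and B1+ 0.59–1.14 in 0.05 steps (72 points). The 100 ms T1
step is a choice: the COV surface is smooth in T1 and its maximum sits on a
range endpoint, so a finer grid moves worst-case values by far less than
the 0.1 pp at which they are quoted; the step is exposed in
`ParamSpace.liver_3t`.

The search enumerates all integer-degree flip-angle multisets between 1°
and 15° (scanner-console limit; repeats allowed since Fisher information is
additive and order-free). Candidate sets are scored in one vectorized pass
— per-FA Fisher contributions are precomputed on the grid and combined by a
counts-matrix product — and ties within 1e-9 COV resolve to the
lexicographically smallest sorted set. The largest default search
(5 angles: 11 628 multisets × 72 grid points) runs in well under a second.

`deoni_angles` provides the classical two-angle reference design (the two
flips at which the signal is 0.71 of the Ernst-angle signal, found by
Brent root-finding on each side of the Ernst angle); with B1+ fixed at 1,
no map noise and a single T1 the exhaustive search reproduces its rounded
pair, which the acceptance suite checks.

## Slice-profile Bloch simulation

Double-angle B1+ mapping inverts the ratio `|S(kα)|/|S(α)|` of fully
relaxed, slice-integrated signals. The slice profile is simulated with the
hard-pulse approximation: the RF waveform is discretized into 256
piecewise-constant samples; at each of 512 positions spanning 3 slice
thicknesses (midpoint sampling) the magnetization alternates a z-precession
under the slice-select gradient (bandwidth = TBW/duration mapped across one
slice thickness) with an x-rotation by the per-sample flip; half the
gradient area is rewound after the pulse (ideal refocusing), and the
complex transverse magnetization is summed across the slice. Relaxation
during and after the pulse is neglected (the mapping sequence is fully
relaxed, TR ≈ 10 s ≫ T1), and bulk off-resonance with free precession to
the echo time is supported but defaults to 0 Hz. Amplitude calibration is
exact for constant-phase waveforms: the signed sample rotations add at
slice center, so the center flip equals the nominal angle to machine
precision (a hard pulse with zero gradient reduces the integrated magnitude
to `3·|sin α|`, which the tests assert exactly).

**Default pulse.** The excitation is a Hanning-windowed sinc, 2 ms, 256
samples, with time-bandwidth 7.0. The vendor pulse behind a product
double-angle sequence is not public, so the default was calibrated to the
operating characteristics such a sequence exhibits at the reference point
(65°/130° pair, B1+ = 0.59, SNR 12): the propagated B1+ factor SD of the
default pulse is 0.158, slightly *below* the ideal-sine closed form 0.161,
which is the regime product sequences report. The resulting ratio
ambiguity angle — the largest true lower flip at which `|S(2α)|/|S(α)|` is
still injective, located by a direct 0.25°-grid scan — is 91.25° for this
pulse (exactly 90° for a hard pulse); sharper pulses push the uncertainty
down and the ambiguity angle toward 90°, softer pulses push both up, so no
windowed sinc matches every published operating characteristic of every
vendor pulse at once. Pulse shape, duration, sample count and TBW are all
constructor parameters.

For repeated evaluation (look-up tables, Monte Carlo, pair search) the
magnitude-vs-flip curve is Bloch-simulated once on a 0.25° grid up to 370°
and monotone-cubic (PCHIP) interpolated; interpolation agrees with direct
simulation to ~1e-4 relative, and exact simulation remains available
through `simulate_slice_signal`.

## B1+ estimation and uncertainty

The ratio LUT tabulates the noise-free ratio at 1° steps of true lower
flip, truncated at the ambiguity angle so it is strictly monotone; the
estimator inverts a measured ratio by monotone-cubic interpolation, and
ratios beyond the tabulated range clamp to the nearest endpoint. Error
propagation uses `σ_R = |R|·sqrt((σ_S/S_kα)² + (σ_S/S_α)²)` and
`σ_B1 = σ_R / (α_nominal[rad] · |dR/dα|)` with the slope at the true lower
flip (central differences, 0.02°).

The Monte-Carlo check adds complex Gaussian noise to both slice-integrated
signals (post-integration — noise is thermal, not per-isochromat), takes
magnitudes, inverts the LUT and reports the SD of signed deviations.
Draws whose noisy ratio exceeds the invertible range (≈ 5 % of draws at
the worst case B1+ = 0.59, SNR 12) are **discarded** by default rather than
clamped: clamping maps each of them to the lowest tabulated flip,
manufacturing outliers of about −0.57 in the B1+ factor that inflate the SD
by ~20 % and bias the mean by −6 %, neither of which practical double-angle
estimators exhibit; with discarding the estimator bias stays near −1 %.
The clamping variant remains available (`on_invalid="clamp"`), and the
discarded fraction is reported. Because the inversion is an arccos-like
nonlinear map, at SNR 12 the truncated-sample MC SD sits a few percent
below the delta-method value; the two agree within Monte-Carlo error once
the relative ratio noise is small (the suite checks this at SNR 100).

The pair search sweeps nominal α (1°–360°), multiplier k (1.25–4) and B1+
(0.59–1.15), excluding pairs whose upper angle exceeds the scanner limit
(130° default) or whose largest on-grid true lower flip exceeds the
ambiguity angle for that k, and minimizes the worst-case error-propagation
SD over the B1+ grid. Randomness everywhere uses counter-based Philox
generators with mandatory seeds.

## T1 fitting and Monte-Carlo validation

Voxel fits minimize `Σ_i (y_i − S(α_i,true))²/σ_i²` with σ_i² from the
total-noise model; repeated flip angles enter as separate residuals.
Initialization is the linearized DESPOT regression of `S/sin α` on
`S/tan α` (slope `E1`), with a mid-range fallback when the slope leaves
(0, 1); bounds T1 ∈ [100, 5000] ms and M0 > 0 keep the optimizer off the
`E1 → 1` ridge. Because σ_i² depends on the parameters, the fit runs one
reweighting round at its own estimate. The per-voxel path uses
`scipy.optimize.least_squares` with the analytic Jacobian; Monte-Carlo
validation and volume fitting use a vectorized batched Levenberg–Marquardt
solver (2×2 normal equations in closed form, multiplicative damping,
accept/reject per problem), cross-checked against the scipy path at 1e-5.

`mc_empirical_cov` perturbs both the signals (σ_SPGR) and the B1+ factor
seen by the fit (σ_B1, independently per measurement — see the diagonality
note above) and reports `100·SD(T1_hat)/T1_true` — the signed-deviation
SD, not an RMSE, so estimator bias is not folded into the precision
number. With correct weights the estimator is asymptotically efficient and
the suite asserts empirical COV within 10 % of the bound at the worst-case
grid corner for three SNRs (10 000 fits each), and an efficiency ratio in
[0.95, 1.15] at SNR 25.

## Synthetic phantom

The phantom emulates what matters for design validation and nothing more:
piecewise-constant T1 (ellipsoidal compartments over a background, values
spread across 700–1200 ms) mimics ROI-scale homogeneous tissue; the B1+
field is a random second-order polynomial min-max normalized to span
[0.59, 1.14] exactly (transmit fields vary smoothly at this scale); M0 is
the nominal scale with a ±5 % smooth modulation. The forward model adds
Gaussian noise at the standard SNR convention. Real data differ in ways
the phantom deliberately omits — fat/water chemical shift, respiratory
motion between breath-holds, incomplete spoiling, receive-field structure,
Rician magnitude statistics at low SNR — so passing the end-to-end
recovery test demonstrates correctness of the estimation chain under the
model's own assumptions, not robustness to those confounds. Volumes are
float32 NIfTI with a JSON sidecar carrying the acquisition metadata
(flip-angle order preserved); tables are plain CSV.

## Problem sizes and determinism

Default problem sizes, chosen so the full suite and the acceptance script
each complete in minutes on a single CPU: 72-point parameter grid; up to
11 628 enumerated 5-angle sets; 512 slice positions × 256 RF samples per
Bloch simulation with one cached 1 481-point magnitude curve per pulse;
10 000 Monte-Carlo draws for both the B1+ SD and the T1-COV validations
(SD standard error ≈ 0.7 %). Everything except the seeded Monte-Carlo
paths is deterministic; the acceptance script's single `--seed` drives all
of its randomness.

## Known limitations

* B1+ map error is modeled per measurement, not as a voxel-shared error
  (see above); likewise the bound assumes unbiased estimation and says
  nothing about accuracy errors from incomplete spoiling, uncorrected
  slice-profile bias in 2D readouts, or magnetization transfer.
* TR is a fixed input (4.1 ms default), not a design variable; joint
  T1/T2 designs are out of scope.
* The ambiguity angle and slice-profile uncertainty depend on the exact
  vendor excitation; the shipped pulse is a calibrated stand-in, and all
  of its parameters are exposed for users who know their pulse.
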