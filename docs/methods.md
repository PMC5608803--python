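# Methods

## Signal model and T1 mapping

The dynamic scan is a spoiled 3D gradient echo (FLASH) in steady state,

    S = M0_eff · sin θ · (1 − E1) / (1 − E1 cos θ),    E1 = e^(−TR/T1),

where `M0_eff` absorbs proton density, receive-coil sensitivity and TE
decay; no explicit T2*/TE term is carried, since the kinetic model only uses
*changes* of R1 and echo-time weighting is common to all frames.  T1 is
mapped per frame by pairing the dynamic scan (TR 8.09 ms, flip 30°) with one
PD-weighted reference scan (TR 100 ms, flip 5°).  The inversion assumes the
reference signal is proportional to `M0_eff·sin θ_REF`, i.e. a fully relaxed
reference.  At TR = 100 ms this is only approximate: the resulting T1
estimate is deterministically low, increasingly so for long T1 (−0.7% at
200 ms, −10% at 3000 ms for the default angles), but remains strictly
monotone in true T1.  The synthetic generator can produce both regimes
(`reference_mode="ideal"` / `"protocol"`), so the approximation is testable
rather than hidden; the test suite asserts exact recovery under the ideal
reference and monotone bias under the protocol reference.

Frames where the inversion's log argument leaves the open interval (0, 1)
(zero/negative difference signals, or signal consistent with infinite T1)
are masked per frame rather than failing the voxel; a voxel is excluded from
fitting when more than 25% of its frames are invalid.  Validity flags
propagate through every derived series and are never silently treated as
numbers.

The pre-contrast rate R10 is the arithmetic mean of the valid baseline R1
samples (first `n_baseline = 3` frames), taken in rate space because the
kinetic model is linear in R1, not in T1.

## SNR

Magnitude-image SNR is μ_signal / σ_corr with σ_corr = σ_Rayleigh / 0.655:
the standard deviation measured in a signal-free background region follows a
Rayleigh distribution whose spread understates the per-channel Gaussian σ by
√((4−π)/2) ≈ 0.655.  The suite closes this loop against the Rician noise
generator: background magnitudes produced as |v + n₁ + i·n₂| with v = 0
recover the generating σ through the 0.655 correction to better than 1% at
n = 10⁶.  Background regions are treated as pure noise.

## Kinetic models and identification

Tissue concentration follows the standard (one-compartment) Tofts model;
concentration maps to relaxation rate through the linear fast-exchange
relation R1(t) = R10 + r1·Ct(t) with default relaxivity r1 = 4.7 s⁻¹mM⁻¹
(gadobutrol at 3 T, configurable).  The relaxivity cancels identically in
the reference-region relation, so only the generator and the validation
oracle depend on it.

The reference-region fit has exactly two free parameters, K^trans,TOI and
v_e,TOI; the reference pair (0.045 min⁻¹, 0.08; skeletal muscle) is fixed
and the ratio R is derived, never free.  Identification uses bounded
trust-region least squares: bounds K^trans ∈ [10⁻⁵, 5] min⁻¹,
v_e ∈ [10⁻³, 1] (spanning the physiological range), initial value
(0.1 min⁻¹, 0.2), cost tolerance 10⁻⁸, at most 500 iterations.
Non-convergence returns the best iterate with `converged=False`; fewer than
10 valid common samples is a flagged failure.  When the peak enhancement of
the tissue curve stays below 3× the baseline R1 noise estimate the result is
flagged `low-enhancement` — the regime (e.g. a fresh, blood-filled lesion)
in which K^trans cannot be reasonably determined.

Time units: K^trans and kep are in min⁻¹, relaxation rates in s⁻¹; series
carry their time unit ("s" or "min") and conversion happens inside the
kernels, which the suite checks by relabelling the axis.

### Quadrature

All convolution integrals are evaluated on the acquisition grid by taking
the integrand piecewise linear between samples and integrating each interval
against the exponential kernel in closed form (interval weights
w0 = Δt[(1−E)−uE]/u², w1 = Δt[u−(1−E)]/u² with u = kep·Δt, E = e^(−u);
series expansion below u = 10⁻³ to avoid cancellation, bounded weights for
arbitrarily large u).  This scheme is exact for piecewise-linear inputs and,
unlike node-based trapezoid of the damped integrand, keeps the
reference-region route and the direct Tofts route numerically consistent at
fast efflux rates: with 13.32 s sampling and kep up to 1.33 min⁻¹ the two
independent fitters agree to <0.3% in K^trans (plain trapezoid leaves ≈2.5%
scheme-dependent disagreement at that corner).  A fine-grid (0.01 s)
convolution oracle bounds the residual discretisation error at ≤0.2% per
sample for the default bolus.

## Synthetic data

The generator chains the same models the analysis inverts: AIF → Tofts →
relaxivity → FLASH signal, plus Rician noise (modulus of signal plus complex
Gaussian noise), so signal-free voxels are exactly Rayleigh and the SNR
definition closes.  What it deliberately does **not** emulate: B1
inhomogeneity, motion, partial volume, k-space/reconstruction effects,
water-exchange (shutter-speed) deviations from linear relaxivity, and
anatomically realistic geometry.  Passing tests therefore demonstrate
correctness of the estimation chain under the model's own assumptions, not
robustness to those real-data effects.

AIF forms: a Weinmann-type biexponential (a₁ = 3.99, a₂ = 4.78 kg/L,
m₁ = 0.144, m₂ = 0.0111 min⁻¹) scaled by the injected dose (default
0.2 mmol/kg, a double dose), and the Parker population form scaled from its
nominal 0.1 mmol/kg.  The bolus arrives at the end of the 3-frame baseline
window (≈40 s); an optional exponential dispersion kernel and a per-dataset
uniform arrival jitter of ±0.9 frame emulate manual tail-vein injection (the
jitter bound is kept just below one frame so the last pre-contrast frame can
never be contaminated).  The reference-region analysis is insensitive to all
of this — switching the AIF form or shifting arrival by 5 s moves estimates
by <0.1% — which is verified as the AIF-independence property.

Noise calibration: `target_snr` sets the per-channel σ to (mean baseline
reference-tissue signal)/SNR, so the Rayleigh-corrected measurement recovers
the target; the default cohort SNR is 80.  `rr_roi_voxels` averages the
reference-region signals over n i.i.d. voxel realisations, emulating the
ROI-mean reference curve the pipeline uses (muscle is homogeneous).  This
matters for bias studies: noise on the reference curve acts as regressor
noise and produces an attenuation-like K^trans bias (≈−6% at kep = 1.33
min⁻¹ with a single-voxel reference at SNR 80), whereas with a 100-voxel
reference ROI the median bias is <0.5% across the recovery grid — which is
why the pipeline always averages the reference ROI signal before inversion.

Phantom: default 32×32×4 grid with rectangular ROIs (label 1 = reference
region, 2 = tissue of interest, 0 = Rayleigh background); the full 205×256
acquisition matrix is supported but not the default, desk-scale grids being
sufficient for validation.  TOI baseline R10 defaults to 1.0 s⁻¹, distinct
from muscle's 0.82 s⁻¹, so the R10,TOI ≠ R10,RR path is always exercised.

Cohort: 5 animals × days (1, 3, 7, 14, 28, 42, 82).  The lesion K^trans day
means (0.02, 0.05, 0.13, 0.14, 0.17, 0.30, 0.14 min⁻¹) implement the
qualitative course low → rising → elevated → maximum (day 42) → decreased;
v_e is flat at 0.30.  Between-animal spread is mean-preserving log-normal
with CV 0.12 for K^trans (a controlled inbred-strain lesion model justifies
a modest CV; an a-priori Welch/Bonferroni power calculation puts the
day-42-vs-14 comparison at ≈94% power for n = 5, comfortably above the 80%
the design is meant to achieve) and CV 0.30 for v_e (deliberately noisy, no
day structure).  All randomness flows from a single seed.

## Statistics

Day-pair testing follows the post-hoc-Bonferroni tradition: all pairwise
two-sample Welch tests on per-animal ROI summary values (medians by
default), each raw p multiplied by the number of pairs (21 for 7 days) and
capped at 1, with tiers at p < 0.05 and p < 0.01.  Groups with fewer than
two usable values are excluded with a logged warning.  An ANOVA gate is
deliberately not applied by default; the Bonferroni adjustment alone
controls the family-wise error, and the suite verifies order- and
relabelling-invariance of the results.  Whether such statistics should run
on per-animal medians or pooled voxels is a genuine design choice; the
default is per-animal medians (n = animals per day), matching the summary
level at which longitudinal animal data are usually reported.

## Problem sizes used in the validation suite

Recovery and equivalence experiments run on a 3×3 grid
K^trans ∈ {0.05, 0.1, 0.2} min⁻¹ × v_e ∈ {0.15, 0.3, 0.5} (kep up to
1.33 min⁻¹, the fast edge of what 13.32 s sampling resolves), 100 noise
replicates per grid point at SNR 80, and 100 replicate cohorts for the power
property; volumetric tests use 16×16×2 and 32×32×4 phantoms.  These sizes
were chosen as the smallest at which the asserted tolerances are meaningful
rather than noise-dominated.

## Known limitations

- The v_e estimate of the reference-region method is known to correlate
  poorly with AIF-based estimates on real data; the suite's 5% agreement
  holds only in the noise-free, model-true regime.
- The fixed muscle parameters enter multiplicatively: any error in
  K^trans,RR rescales all K^trans,TOI by the same factor (R is the invariant
  quantity).
- The T1-inversion bias of the finite-TR reference cancels only to the
  extent that both tissues share the bias; strongly different T1 ranges
  leave a residual effect, which the "protocol" reference mode makes
  measurable.
- No spatial regularisation: voxelwise fits are independent, so maps at low
  SNR are noisy; the ROI-median summaries are the intended readout.
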