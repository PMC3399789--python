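# Methods

This note documents the models, numerical choices and known limits of the
package: what each estimator assumes, what the phantom emulates (and does
not), and where the defaults come from.

## Acquisition model

All modules share one acquisition description (`AcquisitionMeta`), whose
defaults encode the study protocol: 10 diffusion weightings (0, 50, 100, 150,
200, 250, 300, 500, 750, 1000 s/mm²), 80 DCE frames of 3.7 s and 80 DSC
frames of 2 s with the contrast bolus injected after the 20th measurement,
TE = 46 ms for the DSC conversion, 2 mm slices with a 0.2 mm gap, and
0.5 × 0.5 mm in-plane spacing. Dynamic samples are treated as frame-midpoint
values; the bolus arrives at the boundary between frames 20 and 21. Spatial
axes are ordered (x, y, z) with the series axis last; masks live on the image
grid and are validated (never resampled) wherever they are consumed. Volumetry
attributes the inter-slice gap to the nearer slice, so the per-slice extent is
thickness + gap = 2.2 mm.

## Diffusion fitting

The signal model is mono-exponential over all b-values. The log-linear fitter
is weighted least squares of ln S on b with weights S² (exact on noiseless
data; non-positive samples are excluded because their log is undefined). The
default nonlinear fitter runs a damped Gauss–Newton (Levenberg-style)
iteration on (S0, ADC) from the log-linear start, vectorized over voxels; it
keeps non-positive noisy samples, which is what corrects the Rician bias.
Negative fitted slopes are clipped to zero and flagged. Measured behavior on
the protocol: noiseless recovery to machine precision; at SNR 50 the median
absolute error over 10⁴ voxels is ≈2.6%; the median signed bias of the
nonlinear fit stays under 5% down to SNR 10 while the log-linear bias grows
monotonically with noise (−0.3% → −6.9% from SNR 50 to 10).

Whole-tumor ADC is the mean over all finite fitted voxels of the tumor ROI
across slices; rADC divides by the same-examination liver ADC (liver ROIs are
drawn at every scan, so same-timepoint normalization is the natural choice).

## Tofts pharmacokinetics

Concentration is relative enhancement (S − S̄_base)/S̄_base: enhancement is
assumed linear in concentration, appropriate at the low contrast dose of the
protocol. No hematocrit or T1 calibration is applied, so Ktrans is
within-study comparable only; the cohort analysis uses percent change, which
cancels scale (fits are invariant to joint scaling of tissue and AIF).

`tofts_forward` evaluates the convolution on the frame grid by an
exponential-integrator recursion that is exact for a piecewise-linear AIF:
with E = e^(−kep·Δt), J0 = (1 − E)/kep and J1 = (Δt − J0)/kep,

    I_i = E·I_{i−1} + c_{i−1}·J0 + (c_i − c_{i−1})·J1/Δt,   C_t = (Ktrans/60)·I.

Plain trapezoid weights lose up to ~4% when the kernel decays on the
frame-duration scale; the integrator agrees with a 10×-refined quadrature of
the same interpolated AIF to 0.06% across the default parameter ranges. A
useful property of this protocol: because the bolus arrives exactly at a
frame boundary, the linear ramp the interpolation draws across the arrival
interval preserves the bolus integral exactly, which keeps the fit nearly
unbiased; arrival-aware AIF upsampling schemes (log-linear or step-at-arrival
back-extrapolation) were evaluated and are worse everywhere except the most
extreme washout corner, so they were not adopted.

`fit_tofts` is bounded least squares (Ktrans ∈ [0, 5] min⁻¹,
v_e ∈ (10⁻³, 1], start at 0.1/0.3) of the tissue curve against the forward
model; non-convergence is reported in the result, never raised, and an
all-zero tissue curve short-circuits to Ktrans = 0. ROI-mean fitting is the
default for record-level outputs. Measured recovery on fine-grid phantom
curves: ≤0.9% over the default parameter ranges except the (Ktrans = 1 min⁻¹,
v_e = 0.1) corner, where the washout e-folding time (6 s) is close to the
frame duration (3.7 s) and recovery saturates at ≈1.8% — an information limit
of the sampling, not of the optimizer. At image SNR 20 the median absolute
error over the grid is ≈2–3% per parameter.

AIF extraction requires a detectable bolus (post-bolus maximum above 5× the
pre-bolus standard deviation). The biexponential condensation fits amplitudes
and decay rates with the fastest component reported first; on noiseless
model-generated curves all four parameters are recovered within 1%.

## DSC deconvolution

ΔR2\*(t) = −ln(S/S̄_base)/TE is taken proportional to concentration. rBV is
the trapezoidal integral ratio over the full acquisition (no recirculation
correction — the indexes are relative, and percent change cancels scale). The
deconvolution discretizes C_t = Δt·A·(F·R) with A the lower-triangular
Toeplitz matrix of AIF samples (rectangle rule), inverts by SVD with singular
values below 0.2× the maximum zeroed, and reports rBF = max F·R,
MTT = rBV/rBF. The rectangle discretization was chosen over Simpson- and
trapezoid-weighted variants after direct comparison: it is exact on the
one-hot-AIF construction and recovers rBF within ~1% for MTT ≥ 4 s at dt =
2 s with the default first-pass AIF, where the smoothed kernels oscillate or
lose 10–25%.

Known limits, measured and accepted:

* **MTT ≈ dt resolution limit.** A boxcar residue of width equal to the
  sampling interval is not representable by the causal discrete system — the
  tissue curve is in effect a half-frame-shifted AIF, and reproducing a
  half-sample shift in a triangular Toeplitz basis requires oscillatory modes
  that any stable inversion suppresses. At MTT = 2 s = dt the residue peak is
  recovered ~40% low (the exact threshold-0 solve is itself 26% low), with
  corresponding MTT overestimation; from MTT = 4 s upward errors drop below
  1%. Delay-insensitive block-circulant deconvolution, which mitigates this,
  is a deliberate non-goal.
* **Integral quadrature.** Trapezoidal integration of the spiky first-pass
  AIF undercounts it slightly, making rBV high by ≈0.96% independent of MTT
  under the default phantom; with MTT not a multiple of the frame interval
  the tissue curve's kink adds up to ~2%.
* **Baseline noise in long windows.** Over an 80-frame window a baseline
  estimation error of relative size ε shifts every sample, so the AIF
  integral's standard deviation at single-voxel SNR 30 is ~70% of its value.
  Integral indexes at realistic noise are therefore computed on ROI-mean
  curves (the aorta and rim ROIs of the study workflow), where MTT is
  recovered within a few percent at image SNR 30.

Re-convolving the recovered residue reproduces the tissue curve with relative
residual below the truncation threshold, and the estimate is linear in the
tissue curve (rBF, rBV scale; MTT invariant).

## Morphometry

Volume is voxel counting times the voxel volume (in-plane area × 2.2 mm slice
extent); it is exactly additive over the rim/core partition. Diameters use
the caliper convention: maximal pairwise in-plane distance between voxel
centers within a slice (convex-hull accelerated) plus one in-plane voxel
extent, maximized over slices. The relative viable rim is 100 × maximal
in-plane rim thickness / maximal tumor diameter, where thickness is the
largest Euclidean distance from a rim voxel to the necrotic core, measured on
the slice with the largest tumor diameter among slices containing the core —
measuring on off-center slices would be inflated where the core vanishes, and
using the rim region's own Feret diameter would degenerate to the tumor
diameter. Two conventions are fixed for degenerate inputs: a tumor with no
core is all rim (100%), an empty rim is 0%. On digitized concentric spheres
(8 mm tumor, 2 mm rim, 0.5 mm grid) the volume is within 0.6% of analytic,
the necrosis fraction within 0.5 percentage points of 100·(6/8)³, and the
measured rim thickness within one voxel of 2 mm.

## Statistics

The omnibus test is the tie-corrected Kruskal–Wallis H with a chi-square
(k − 1) reference; all-identical data (where the tie correction is 0/0)
returns H = 0, p = 1 by convention, and an exact permutation p is available
for total n ≤ 15. Post-hoc testing runs all k(k−1)/2 two-sided Wilcoxon
rank-sum tests (normal approximation with tie correction) with Bonferroni
adjustment min(1, p × k(k−1)/2). Tests enumerate every 3-group dataset over a
small integer alphabet — which realizes every tie pattern at those sizes —
against an independently coded brute-force H; the literal "all integer
datasets" family is unbounded, so the alphabet version is the exhaustive
check actually run.

Stepwise selection alternates forward entry (smallest partial-F p-value,
evaluated as the squared-t of the added coefficient, below entry_p = 0.05)
with backward elimination (any included p above exit_p = 0.10), to a fixed
point; the 0.05/0.10 defaults are the classical stepwise defaults of the
statistics packages this procedure originates from. OLS fits come from
statsmodels; rank-deficient additions are skipped with a logged warning. For
a one-predictor final model the reported r is the signed sample correlation
(identical in magnitude to the model's multiple R). Calibration facts worth
knowing: the omnibus type-I rate at the study's group sizes is ≈4.2–4.4%
(slightly conservative, as expected of the chi-square approximation), and
with five independent null candidates the probability of an empty stepwise
selection is 0.95⁵ ≈ 77% — per-candidate entry is α-controlled, familywise
entry is not, which is inherent to stepwise selection.

The study-level analysis compares the percent change from baseline of
{tumor volume, rADC, Ktrans, v_e, rBV, rBF} across the four arms at each
post-treatment timepoint, then regresses the 12 d volume change on the five
imaging changes within the combination-therapy arm (n = 12 supports 5
candidates). The repeated-measures general linear model over time is a
non-goal; the per-timepoint nonparametric path covers the fixed-timepoint
claims.

## Phantom and cohort generator

The phantom digitizes voxel-center geometry: tumor ellipsoid, inner core
ellipsoid (radii reduced by the rim thickness), liver box, z-aligned aortic
cylinder; any region under 10 voxels is rejected, mirroring the ROI size
floor used in practice. Region-constant truth values default to generic
soft-tissue/tumor literature ranges (viable rim ADC 0.9 × 10⁻³ mm²/s, Ktrans
0.25 min⁻¹, v_e 0.35, F·MTT = 6 a.u.; necrotic core ADC 2.2 × 10⁻³, near-zero
perfusion; liver in between) — simulator defaults, not measurements. The DSC
truth is centrally consistent by construction (BV = F·MTT wherever F > 0).

Noise is Rician (Gaussian on two quadrature channels, magnitude taken), the
correct model for magnitude MRI and the reason the ADC fitter's bias behavior
is testable. The DCE AIF is the classical biexponential population decay
(a₁ = 3.99, a₂ = 4.78 kg/l; m₁ = 0.144, m₂ = 0.0111 min⁻¹) with arrival fixed
at the known injection frame; the DSC AIF uses the same functional form with
fast decay rates (20 and 6 min⁻¹) so the first pass clears within the 160 s
acquisition — physically right for a susceptibility first pass and necessary
for the integral indexes to be well defined on the acquired window; the sharp
bolus also keeps the deconvolution matrix well conditioned (condition number
≈5 after cropping the pre-bolus zeros). Tissue concentrations are integrated
on a 20× fine grid with trapezoid end-correction (verified against the
analytic biexponential⊛exponential closed form to <0.01%), deliberately
independent of the fitters' frame-grid quadrature so the phantom can serve as
their oracle.

The cohort generator produces per-subject records as baseline × group effect
factor × mean-one lognormal noise (σ² = ln(1 + CV²)), drawn independently per
subject, timepoint and quantity; CV defaults to 0.15. The default effect
trajectories encode only the signed dynamics of this treatment model —
perfusion collapse at 4 h under the vascular-disrupting agent with rebound by
2 d when given alone but sustained suppression under the combination,
transient permeability reduction, ADC rise as necrosis accumulates, growth
delay and a thinner viable rim under the combination — with magnitudes as
configuration, and the group sizes default to the 10/11/11/12 randomization.
What the phantom does not emulate: realistic organ anatomy, respiratory
motion, partial-volume effects at the aorta, bolus delay/dispersion between
aorta and tumor, contrast leakage in DSC, and within-region parameter
heterogeneity. Passing recovery tests therefore demonstrates correctness of
the estimators under their stated models, not robustness to those real-data
effects.

## Pipeline

`run_pipeline` derives every random stream deterministically from the single
config seed (numpy `SeedSequence` spawn keys per stage), so reruns are
bit-identical; the manifest records config, seed, package version, stage log
and SHA-256 checksums. Cohort mode writes truth-derived records for all
subjects and simulates/fits full images for a configurable subset (default
one subject), keeping the 44-animal × 5-timepoint emulation at desk scale;
the per-module recovery tests bound the gap between fitted and truth-derived
records. Stage failures raise with the stage name; an unknown config key is
rejected before any computation. Default problem sizes — a 48 × 48 × 12 voxel
grid, ROI-mean kinetic fits, and 200–1000 Monte-Carlo replicates in the
statistical checks — were chosen so a full validation run completes in
minutes on a single desktop core.
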