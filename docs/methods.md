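# Methods

## Scope and data model

The package analyses a dynamic contrast-enhanced (DCE) MRI experiment for
blood–brain-barrier (BBB) permeability: a T1-weighted 3D spoiled-gradient-echo
(VIBE-type) series acquired continuously over a gadolinium injection, together
with a pre-contrast T1 map, a B1 (flip-angle scale) map, anatomical ROI labels
and drift-phantom labels — all assumed already co-registered on one voxel
grid. Registration, atlas warping and the multi-parametric mapping that
produces the B1/T1 maps are upstream of this package and out of scope, as is
any T2*/TE modelling (TE is recorded but the SPGR model deliberately omits
echo-time decay; at TE < 1 ms it is negligible relative to the T1 effect).

Default acquisition parameters: TR = 2.56 ms, TE = 0.86 ms, flip angle 15°,
432 dynamic volumes at 2.4 s each (~17 min), 10 pre-contrast baseline volumes,
dose 0.05 mmol/kg, gadoterate r1 relaxivity 3.6 L·mmol⁻¹·s⁻¹ at 3 T
(configurable; the agent's nominal value is not universal across field
strengths). Volume k is stamped at t = k·dt; bolus arrival is pinned to the
start of volume index `n_baseline`.

## Arterial input function

No subject-specific AIF is measured in this protocol (no large vessel is
reliably inside the imaging slab, and the temporal resolution is low), so
simulator and fitter share one population bi-exponential curve,

    Cp(t) = D · (a1·e^{−m1(t−t0)} + a2·e^{−m2(t−t0)}),  t ≥ t0,

with the classic adult population constants a1 = 3.99, a2 = 4.78 kg/L,
m1 = 0.144, m2 = 0.0111 min⁻¹ and D the dose in mmol/kg. Using the same curve
on both sides isolates the Patlak machinery: K-trans estimates are then exact
on noiseless data, and any real-data AIF misspecification scales both groups
equally in a group comparison. This is the standard compromise for
low-temporal-resolution BBB protocols; it is a deliberate limitation, not an
oversight.

## Forward model and synthetic cohorts

The digital phantom is a 32×32×12 grid at 2.5×2.5×5 mm (the 5-mm slice
matches the target protocol; the in-plane size keeps per-subject simulation
in the seconds range). It contains a parenchyma box, ten disjoint 60-voxel
ROIs named for the ten anatomical regions of the group analysis, and three
gel tubes outside the head. Tissue enhancement follows the forward Patlak
equation with the cumulative integral evaluated by the trapezoid rule on the
sampled grid — the same quadrature the fitter uses, which makes the
forward/inverse loop exact to machine precision in the absence of noise.
Concentration shortens T1 linearly in rate (R1(t) = R1₀ + r1·Ct) and maps to
signal through the SPGR steady state with a smooth, deterministic B1 ramp
spanning 0.92–1.08. Phantom tubes take no contrast: their true signal is
constant up to gain drift and noise.

Corruptions: multiplicative linear gain drift (fraction per minute, applied
to every voxel) and additive Gaussian noise on the magnitude signal (default
σ = 0.3 against a brain baseline of ≈15.3, i.e. SNR ≈ 50; a Rician option
exists but Gaussian is the default because at this SNR the difference is
negligible and Gaussian keeps inverse-model tests exact).

Cohorts: group A (reference genotype, n = 19) and group B (risk genotype,
n = 17). Per-ROI group-mean K-trans defaults are the observed modal positions
of the ten regions (0.52–1.90 ×10⁻³ min⁻¹), and the group-B shifts are the
corresponding observed differences — subtle, mostly positive in hippocampal
and subcortical regions. Per-subject ROI means are drawn with between-subject
CV 0.4 (chosen to reproduce the reported between-subject SD scale), and
within-ROI voxel values with CV 0.5 around the subject mean, clipped at zero.
The within-ROI spread is what gives histograms realistic width and produces
the "higher mean → broader distribution → lower normalized peak" mechanism;
it is kept separate from the between-subject CV because the two act at
different levels of the hierarchy.

### Sampling-level cohort simulator

Cohort-scale statistical studies (type-I-error calibration over 200 cohorts,
direction-of-effect over 100) would require thousands of full 4-D image
simulations. `sample_cohort_metrics` instead draws per-subject per-ROI voxel
K-trans values directly from the generative hierarchy above — adding a
per-voxel noise floor of 0.4×10⁻³ min⁻¹ standing in for Patlak estimation
noise, and uniformly jittered ROI sizes (150 ± 30 %) as the ANCOVA
covariate — and feeds them through the real histogram and statistics code.
What this validates is the statistical pipeline (histogram metrics, outlier
removal, ANCOVA calibration, effect direction) under the cohort's generative
assumptions; the imaging chain itself (conversion, drift, fitting) is
validated separately at the subject level, where exactness and recovery can
be checked against stored voxel-level truth. The sampler does not emulate
spatial noise correlation, motion, or fit failures, so passing cohort tests
say nothing about those real-data effects.

## Concentration conversion

Per voxel and frame, with α_eff = b1·α and E1₀ = exp(−TR/T1₀):

    A    = (1 − E1₀) / (1 − E1₀ cos α_eff)
    y(t) = (S(t)/S0) · A
    E1(t)= (1 − y) / (1 − y cos α_eff)
    R1(t)= −ln E1(t) / TR      (s⁻¹)
    C(t) = (R1(t) − R1₀) / r1  (mmol/L)

S0 is the mean of the pre-contrast baseline volumes. Voxels with S0 ≤ 0,
T1₀ ≤ 0 or B1 ≤ 0 are masked; individual voxel-frames whose implied E1 leaves
(0, 1) are flagged invalid and excluded from the regression rather than
clamped — clamping would bias exactly the slow late-time signal the Patlak
slope lives on. Voxels with fewer than 5 valid post-bolus frames are dropped
from the maps. Counts of both are logged and surfaced in the per-subject QC.

Smoothing: a Gaussian kernel parameterised by FWHM (the dominant neuroimaging
convention for "4-mm isotropic"; σ = FWHM/2.3548 per axis, divided by the
voxel size) is applied spatially — each time frame independently — to the T1
map and the dynamic data before conversion, with nearest-edge handling.
Smoothing does not commute with the nonlinear conversion, so validation
studies that compare fitted maps against voxel-level truth run with
`fwhm_mm = 0`; the 4-mm default is a bias/variance trade intended for noisy
real data, and a dedicated test pins down that the bias it introduces on the
sharp-edged digital phantom stays bounded.

## Drift control

Tube voxels (any phantom label > 0) are averaged per frame; a polynomial in
time (default order 1) is fitted by ordinary least squares and normalized to
mean 1 over the baseline window. Linear is the default because a ~17-minute
acquisition drifts approximately linearly and higher orders risk absorbing
genuine contrast dynamics if a tube mask leaks into tissue. Correction
divides every frame by the fitted multiplier; because the multiplier is
renormalized to the baseline window, any residual constant factor cancels in
S(t)/S0 and the conversion is unaffected. Both a `correct` and a
`monitor`-only mode are exposed, since drift may be tracked without being
removed; `correct` is the default.

## Patlak fitting

Each voxel's concentration series is regressed on [Cp(t), ∫₀ᵗCp] with no
intercept over the post-bolus frames (a configurable start offset can skip
bolus-passage non-equilibrium; default 0). The direct bilinear form is
preferred to the classic ratio-form Patlak plot (Ct/Cp vs ∫Cp/Cp) because the
latter divides by small late-time Cp; on noiseless data the two are
algebraically identical, and a test asserts that equivalence. Negative
estimates are returned unclamped — they are legitimate draws from the
estimator's null distribution and carry information for the ROI histograms.
Fit quality is the uncentered R² (total sum of squares about zero, since the
model has no intercept). Rank-deficient designs (relative condition cutoff
1e-10) exclude the voxel with a logged count.

## Histogram metrics

ROI K-trans values are reported in ×10⁻³ min⁻¹. Bins are fixed across
subjects and groups — width 0.1×10⁻³ min⁻¹ over [−2, 10]×10⁻³ min⁻¹, covering
the observed modal positions plus noise-driven negatives — because
comparability of heights across subjects requires a common grid; both are
configurable and recorded in outputs. Counts are normalized to percent of the
ROI voxel count (the stated purpose of normalization is ROI-size
comparability, and percent-per-bin is consistent in magnitude with reported
peak heights of 2–10, though the original unit is not documented).
`peak_height` is the modal bin's percent, `peak_position` its centre; ties
break toward the lowest bin for determinism.

## Group statistics

Outlier removal is a ROUT-style robust FDR screen per group, per ROI, per
metric: residuals about the median, robust SD from the 68.27th percentile of
absolute residuals inflated by n/(n−1), two-sided t-tail probabilities
(df = n−1), Benjamini–Hochberg step-up at Q (default 1 %, the originating
software's default; the protocol names the procedure but not Q). With n < 3
nothing is removed.

The ANCOVA fits metric ~ intercept + group + covariate by OLS with the ROI
voxel count (centred) as covariate and tests the group term with the
single-df partial F; adjusted means are evaluated at the grand covariate
mean. A constant covariate degrades to one-way ANOVA with a warning. No
multiple-testing correction is applied across the ten regions — the design
treats the genotype contrast as a single hypothesis at α = 0.05 — but the
summary also emits the directional count of regions where group B's mean ROI
K-trans exceeds group A's, which under the null is binomial around 5/10.

Cohen's d uses the unweighted root-mean-square of the two SDs rather than the
n-weighted pooled SD. The two conventions differ visibly when group SDs are
unequal (e.g. means 9.95 vs 7.41 with SDs 9.9 vs 3.1 give 0.35 unweighted but
0.34 n-weighted), and the unweighted form is the one consistent with the
published effect sizes this package reproduces. d is reported unsigned, with
the signed group-B-minus-group-A mean difference kept in a separate column.

## Numerical and testing choices

* Shared trapezoid quadrature makes the noiseless forward→fit loop exact;
  tests assert 1e-9 relative agreement (with a 1e-12 absolute floor for truth
  values clipped to zero by the non-negativity constraint).
* Validation problem sizes: subject-level tests run a 120-volume series on
  the default grid (the fit is linear in frames, so shortening the series
  changes conditioning, not correctness); the SNR-50 recovery study uses the
  full 432-volume protocol on a 2160-voxel uniform-truth ROI; cohort-scale
  calibration uses the sampling-level simulator (200 and 100 cohorts).
* Determinism: every stochastic element flows from integer seeds through
  `numpy.random.default_rng`; identical spec + seed gives bit-identical
  datasets, and per-subject seeds are drawn from the cohort seed.
* Degenerate inputs: empty masks, missing ROIs, constant covariates,
  all-outside-range histograms and rank-deficient designs all raise or warn
  explicitly rather than returning silent NaNs; cohort summarisation logs and
  continues past a broken ROI.

## Known limitations

* No water-exchange, T2*, motion or partial-volume modelling; the simulator's
  noise is spatially white, so smoothing looks more beneficial on synthetic
  data than it is on real data with correlated noise.
* The population AIF is a stand-in; absolute K-trans values inherit its
  scale, though group contrasts do not.
* The B1 field is a smooth deterministic ramp, not a measured transmit map;
  it exercises the correction path but not B1 estimation error.
* ROUT here is a location-model variant (robust regression against a
  constant); it reproduces the screening behaviour, not the originating
  software's nonlinear-regression internals.
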