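# bbbdce

Blood–brain-barrier (BBB) permeability analysis of dynamic contrast-enhanced
MRI (DCE-MRI): voxel-wise Patlak fitting of K<sup>trans</sup> and V<sub>p</sub>
from a T1-weighted spoiled-gradient-echo dynamic series, with B1/T1-corrected
signal-to-concentration conversion and phantom-based scanner-drift control;
ROI K<sup>trans</sup> histogram metrics (normalized peak height and peak
position); and covariate-adjusted two-group statistics (ANCOVA with ROI volume
as covariate, robust outlier removal, Cohen's *d*).

The package is aimed at quantitative-MRI researchers studying subtle, diffuse
BBB leakage — for example comparing carriers of different APOE genotypes in
a healthy cohort — where per-voxel effects are far below single-subject
detectability and the analysis must squeeze a weak signal out of a ~17-minute
acquisition without being swallowed by scanner drift or flip-angle
inhomogeneity. Because such participant data are rarely shareable, a
synthetic digital-phantom cohort generator with known ground-truth kinetics
is a first-class part of the package: every stage of the pipeline is
validated against simulated truth.

## Model

Tissue contrast-agent concentration follows the Patlak model for slow,
effectively unidirectional leakage across the BBB:

```
Ct(t) = Ktrans · ∫₀ᵗ Cp(τ) dτ  +  vp · Cp(t)
```

where `Cp(t)` is the plasma concentration (a dose-scaled population
bi-exponential arterial input function), `Ktrans` (min⁻¹) is the transfer
constant — the proxy for BBB permeability — and `vp` is the fractional plasma
volume. The dynamic signal is converted to concentration by inverting the
spoiled gradient-echo steady state

```
S = M0 · sin(b1·α) · (1 − E1) / (1 − E1·cos(b1·α)),   E1 = exp(−TR/T1)
```

using the pre-contrast T1 map and the B1 (flip-angle-scale) map, with
`R1(t) = R1₀ + r1·C(t)`. Each voxel is then fitted by ordinary least squares
of `Ct` on the two regressors `[Cp, ∫Cp]` (no intercept) over the post-bolus
frames. Gain drift, estimated from gel phantom tubes in the field of view,
is divided out of the signal first.

Per subject and ROI, the K<sup>trans</sup> histogram (fixed bins, counts
normalized to percent of ROI voxels) is reduced to its **normalized peak
height** (percent in the modal bin — diffuse damage broadens the distribution
and lowers it) and **peak position** (modal bin centre, ×10⁻³ min⁻¹ — a global
permeability shift raises it). Groups are compared per ROI by one-way ANCOVA
with the ROI voxel count as covariate, after ROUT-style robust FDR outlier
removal, with effect size

```
d = |m_a − m_b| / sqrt((s_a² + s_b²) / 2).
```

## Worked example

Simulate one subject on the default 32×32×12 digital phantom (ten 60-voxel
ROIs, three drift-phantom tubes, additive noise σ = 0.3), fit it, and extract
ROI metrics:

```python
from bbbdce import (AcquisitionParams, AifParams, generate_subject,
                    process_subject, subject_roi_metrics)
from bbbdce.synthetic import default_phantom

acq = AcquisitionParams(n_volumes=120)          # shortened series for the demo
phantom = default_phantom(noise_sigma=0.3)
truth = {rid: 1.0e-3 + 0.1e-3 * rid for rid in range(1, 11)}   # min^-1
ds = generate_subject(phantom, acq, AifParams(), truth, truth_vp=0.02, seed=1)
res = process_subject(ds, fwhm_mm=0.0, drift_mode="correct")
print(subject_roi_metrics(ds, res.maps).head(3))
```

```
         roi_name  voxel_count  peak_height  peak_position  roi_mean_ktrans
 left_hippocampus           60     8.333333           1.15         1.255502
right_hippocampus           60    10.000000           1.65         1.256461
      left_wm_acc           60     8.333333           1.65         1.160517
```

`peak_height` is percent of ROI voxels in the modal bin; `peak_position` and
`roi_mean_ktrans` are on the ×10⁻³ min⁻¹ scale (left hippocampus truth here
is 1.1×10⁻³ min⁻¹; the noisy single-subject ROI mean lands at 1.26).

Cohort-level comparison (sampling-level simulator, 19 vs 17 subjects with the
default subtle hippocampal/subcortical shift):

```python
from bbbdce import GroupEffectSpec, sample_cohort_metrics, summarize_table
metrics = sample_cohort_metrics(GroupEffectSpec(rng_seed=1))
table = summarize_table(metrics)       # 10 ROIs x 2 metrics
print(table[table.roi_id == 1].round(3))
```

```
        roi_name        metric  mean_a  sd_a  mean_b  sd_b  ancova_p  cohens_d
left_hippocampus   peak_height   8.378 1.894   8.918 2.209     0.671     0.263
left_hippocampus peak_position   1.034 0.556   1.126 0.595     0.675     0.160
```

A subtle, non-significant shift of the expected direction — higher peak
position in the shifted group — exactly the regime the histogram metrics and
effect sizes are designed to summarise. Standalone effect sizes from group
summaries:

```python
from bbbdce import cohens_d
round(cohens_d(4.66, 1.8, 4.41, 1.5), 2)   # -> 0.15
```

A command-line interface chains the stages over NIfTI/CSV files:

```bash
bbbdce simulate --config config.yaml --out sim/ --seed 1
bbbdce fit --manifest sim/manifest.csv --out fit/
bbbdce stats --metrics fit/metrics.csv --q 1.0 --out stats/
bbbdce run-all --config config.yaml --out results/ --seed 1
```

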