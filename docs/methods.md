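# Methods

## Curve model and end-systole detection

A study is a set of 16 segmental time-volume curves on a shared grid, time
in % of the RR-interval with t = 0 at QRS onset, one full cycle in
[0, 100] %RR, volumes in ml. The curves are treated as piecewise linear.
Before analysis every study is resampled onto a uniform grid of
`n_samples = 201` points (0.5 %RR resolution) by linear interpolation;
curves that do not span the full cycle are clamped at their boundary values
with a logged warning. 201 points comfortably exceeds the frame count of a
3D-echo acquisition (typically 10–30 frames per cycle), so resampling adds
resolution to the analysis grid without inventing structure beyond the
piecewise-linear model.

End-systole — global (on the summed curve) and segmental — is the discrete
argmin on this grid. No sub-sample (e.g. parabolic) refinement is applied:
the achievable timing resolution is the grid step and is reported as such.
Ties are broken toward the earliest time; this deterministic rule biases an
exactly-tied segment toward the "pre" class and is the reason a flat
(akinetic) segment is assigned end-systole at t = 0.

## Metrics

* **SDI**: standard deviation of the 16 segmental end-systolic times.
  Default is the sample SD (divisor N−1); the population divisor is
  available (`sdi_divisor="n"`) because the convention of the original
  clinical analysis software is unpublished.
* **L-E**: latest minus earliest segmental end-systolic time.
* **Segmental STV**: trapezoidal integral of `max(V(t) − V_min, 0)` between
  segmental and global end-systole. Both endpoints are grid points after the
  shared resampling, so no partial intervals arise; the clamp at zero guards
  against stored minima marginally above interpolated values. Segments are
  classified pre / post / synchronous by the sign of `t_seg − t_glob`;
  synchronous segments (exact grid tie) form their own class with zero area
  and are counted in neither sum. Pre-STV, Post-STV and total STV are the
  class sums; total = pre + post is an identity of the partition.
  Post-STV never wraps across the cycle boundary: events around end-diastole
  are outside the model.
* **Global function**: EDV and ESV are the maximum and minimum of the summed
  curve; EF = 100 × (EDV − ESV)/EDV. A study with zero EDV is rejected.

Units: %RR on the 0–100 scale throughout; STV in ml × %RR ("ml%").

## Cohort statistics

Response to CRT is a ≥10% ESV reduction at follow-up (boundary inclusive);
Δ-ESV = 100 × (ESV_fu − ESV_base)/ESV_base is the continuous measure.

The ROC curve is empirical over all distinct score thresholds; AUC is the
trapezoidal area, identical to the Mann–Whitney concordance probability with
ties counted ½ (verified against exhaustive pair counting). The 95% CI uses
the Hanley–McNeil standard error. The operating cutoff maximizes the Youden
index J = sens + spec − 1, ties resolved toward higher sensitivity; the 2×2
counts are retained in all outputs so the percentage values can be audited.
Correlated AUCs (two metrics on the same patients) are compared with the
DeLong test (midrank placements, normal approximation); identical score
vectors return p = 1. The positive-test direction is configurable per metric
and defaults to higher-is-positive for all four indices; it is never
auto-flipped — an anti-predictive metric simply shows AUC < 0.5.

Group comparisons use Student's pooled-variance t-test by default (Welch by
flag), paired t-tests within groups baseline vs follow-up, and Pearson
correlation (t-transform, n−2 df) against Δ-ESV. Reproducibility uses
Bland–Altman analysis: bias = mean difference, limits of agreement
bias ± 1.96 × sample SD of the differences.

Degenerate inputs (single-class cohorts, zero-variance scores, groups
smaller than 2) are rejected or suppressed to NaN with a warning rather than
silently returning numbers.

## Synthetic data generator

Each segmental curve is
`V(t) = v_min + amplitude · w((t − delay) mod 100) + ε`, clipped at 0, where
`w` is a piecewise raised cosine with minimum 0 at the reference
end-systolic time (default 40 %RR) and value 1 at both cycle ends, so the
circular delay shift is continuous. An `asymmetric_systole` variant squares
the descent limb (faster volume loss than recovery). `amplitude` is the
volume excursion and serves as the contractility surrogate: `amplitude = 0`
is an akinetic segment. Noise ε is additive white Gaussian per sample
(default 0.02 ml), independent across segments — a simplification: real
border-detection output is temporally smooth, and white noise at much higher
levels makes the discrete argmin wander across the flat waveform minima.

Ventricular volume is distributed over segments with basal : mid : apical
weights 1.4 : 1.0 : 0.65 (log-normal jitter), so basal segments dominate the
STV sums as they should.

### Cohort model

The default CRT cohort has 20 responders and 8 non-responders. Per-group
baseline distributions (truncated normals; a moment-matched log-normal is
available for strongly right-skewed quantities):

| parameter | responders | non-responders |
|---|---|---|
| EDV (ml) | 195 ± 45, ≥ 90 | 176 ± 60, ≥ 90 |
| EF (%) | 19 ± 8 in [5, 38] | 20 ± 11 in [5, 38] |
| baseline Pre-STV target (ml%) | 51.4 ± 51.2, ≥ 2 | 5.2 ± 6.8, ≥ 0.3 |
| delayed segments | 4–7, &#124;delay&#124; 12–28 %RR | 2–4, &#124;delay&#124; 8–18 %RR |
| hypokinetic fraction of delayed | 0.1 | 0.9 |
| follow-up ESV change (%) | −22 ± 7, ≤ −13 | +3 ± 5, ≥ −5 |

Every segment additionally carries a small timing jitter (SD 1.5 %RR), and a
per-patient severity factor (log-normal, σ = 0.3) scales the delay
magnitudes, reproducing the wide between-patient spread of SDI and L-E seen
in heart-failure cohorts. Half of a patient's delayed segments contract
early, half late: the late, strong group holds the global minimum late,
which is what lets the early group accumulate pre-systolic volume loss —
scaling only early amplitudes would drag the global minimum toward them and
collapse Pre-STV, so the per-patient calibration that matches the drawn
Pre-STV target scales the whole delayed group's amplitudes (three measured
passes on a noiseless prototype, clamped factors). Delays are kept small
enough that all segmental minima stay inside the cycle.

Follow-up: responders' delays shrink by the CRT homogenization factor
(default 0.85) and all volumes are scaled to the drawn ESV change;
non-responders keep their baseline activation pattern (so their follow-up
SDI/L-E are unchanged) and drift in ESV per their effect distribution. The
drawn effect distributions keep both groups clear of the 10% response
boundary, so the measured labels reproduce the generator's ground truth
despite measurement noise. All draws derive from one root seed
(`SeedSequence([seed, patient_index])`), and per-study noise seeds are
recorded in the ground-truth output.

### What the generator does and does not emulate

It reproduces: smooth unimodal segmental traces, the basal-volume weighting,
both phenotypes (delayed-strong and delayed-hypokinetic segments), group
separation in Pre-STV/SDI/L-E with realistic overlap, reverse remodelling
and its correlation with baseline dyssynchrony, and seeded reproducibility.
It does not emulate: valve timing and isovolumetric phases, temporally
correlated measurement error, scar/ischemia geometry, mitral regurgitation,
or multi-beat variability. Synthetic Post-STV is right-skewed and higher in
responders than the clinical regime (the late strong cluster feeds it);
Post-STV is not calibrated to any target. Passing tests therefore certify
the algebra and statistical machinery of the pipeline on this model class,
not clinical performance on real 3D-echo data.

## Numerical choices

* Trapezoidal integration on the shared grid (exact for the piecewise-linear
  curve model); verified against a 10⁴-subinterval Riemann-sum oracle to
  0.5% relative.
* Partition identity pre + post = total holds to 1e−9 relative.
* Discrete argmin ties → earliest time; resampling to a finer grid moves a
  segmental end-systole by at most one coarse grid step.
* Truncated-normal sampling by rejection (the default truncations keep the
  accepted mass large); log-normal option is moment-matched to (mean, SD).
* DeLong variance from sample covariances (ddof = 1); zero-variance
  difference returns p = 1 for a zero AUC difference.
* Analysis problem sizes: 201-point grid, cohorts of 28 patients, 100-seed
  replication in the end-to-end check, 1000-replicate null calibrations of
  the t-test and DeLong test.

## Known limitations

* The earliest-tie argmin rule makes a perfectly flat segment's end-systole
  t = 0; with measurement noise this is irrelevant, but exactly-flat
  noiseless segments move SDI/L-E by construction.
* Pre-STV calibration matches the drawn target only approximately (clamped
  factors, drifting global end-systole); achieved group means track the
  targets, individual patients can deviate.
* The Hanley–McNeil CI and the DeLong normal approximation are asymptotic;
  at n = 28 they are indicative, as in the clinical setting they mirror.
* No sub-frame end-systole interpolation: timing resolution is the grid
  step (0.5 %RR by default).
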