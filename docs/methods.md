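# Methods

## Problem

Mean apparent diffusion coefficient (ADC) over a tumour region of interest
(ROI) is a candidate imaging biomarker of early treatment response. Whether
an observed test–retest change ΔADC% in an individual lesion is meaningful
depends on the measurement uncertainty of that particular measurement,
which varies strongly with ROI size and ADC heterogeneity. This package
implements a data-driven model of that uncertainty, fits it to observed
repeatability data by maximum likelihood, checks it by a χ² goodness of
fit, and uses it to standardise repeatability values and to build look-up
charts of expected uncertainty versus ROI size and histogram width.

All ADC values are handled in units of 10⁻⁵ mm²/s (so 1.09×10⁻³ mm²/s is
written 109), the convention of the printed liver-DWI numbers this package
reproduces.

## Repeatability statistic

For test/retest mean ADC values D₁, D₂ of the same ROI,

    R₁₂ = 2 (D₁ − D₂) / (D₁ + D₂) × 100        (percent)

is the symmetric percentage change; the same form with voxel counts gives
ΔVOL%. Cohort reproducibility is summarised as the width of the 95%
confidence bound, 1.96 × SD of the per-pair values. The standard deviation
uses the population form (ddof = 0) by default: this is the convention that
reproduces the published cohort statistics this package ships as a fixture
(SD ΔVOL% = 8.2 and CoV = 5.3 obtain with ddof = 0 and not with ddof = 1);
`ddof` is exposed everywhere for the sample form. The within-subject
coefficient of variation is the standard test–retest form,
100 × SD(D₁ − D₂) / (√2 × grand mean).

## Uncertainty model

First-order propagation of session-mean errors σ_D1, σ_D2 into R₁₂ gives

    ε(σ_D1, σ_D2) = 400 √(D₁² σ_D2² + D₂² σ_D1²) / (D₁ + D₂)²   (percent).

The predicted uncertainty of a pair combines three sources in quadrature:

    ε²_R12 = β² ε(w₁/√N₁, w₂/√N₂)² + ε(σ_fix/√N₁, σ_fix/√N₂)² + ε²_sys

* **β** (dimensionless) inflates the histogram-derived standard error of
  the ROI mean, w/√N (w = ADC histogram SD, N = voxel count). β > 1
  captures spatial correlation and heterogeneity effects that make the
  naive standard error optimistic.
* **σ_fix** (10⁻⁵ mm²/s) is a fixed per-voxel fitting dispersion. It enters
  through its contribution σ_fix/√N to each session's mean-ADC error. The
  alternative reading — using σ_fix un-scaled as a session-mean error —
  would predict ~90% uncertainty for every ROI at the magnitude the model
  fits (σ_fix ≈ 70), contradicting the observed few-percent spreads and
  the plateau of uncertainty against ROI size; the √N scaling is therefore
  adopted and flagged as an interpretation.
* **ε_sys** (percent) is the irreducible systematic (scanner/session)
  error.

Nested variants hold parameters at zero: `sys_only` (ε_sys), `two_param`
(β, ε_sys), `three_param` (all three). Look-up grids tabulate ε_R12 for
symmetric pairs (D₁=D₂=D, N₁=N₂=N, w₁=w₂=SD) and need a nominal ADC level
because the propagation depends on D; the default is 109, the cohort
average. Above roughly 2000 voxels (22.5 cm³ at the default
1.5 × 1.5 × 5 mm geometry) the size benefit plateaus.

## Likelihood, fitting, goodness of fit

Observed R₁₂ values are modelled as independent zero-mean Gaussians with
per-record SD ε_i from the model, giving (constants dropped)

    NLL = Σ_i [ ln ε_i + R₁₂ᵢ² / (2 ε_i²) ].

The Gaussian form is consistent with the model's own χ² usage (χ² ≈ dof
when standardised). Fitting minimises the NLL over log-parameters
(positivity by construction) with Nelder–Mead from 8 seeded starts (one
moment-based, the rest log-uniform over β ∈ [0.3, 30], σ_fix ∈ [1, 500],
ε_sys ∈ [0.2, 30]), NLL tolerance 1e−8, ties broken toward the smallest
parameter norm, followed by a quasi-Newton polish; this reproduces the
closed-form `sys_only` MLE ε̂ = √(mean R₁₂²) to better than 1e−6 relative.
Motion-flagged records are excluded from fitting — motion is not a fixed,
modellable error — but are retained in evaluation and standardisation,
where they surface as outliers.

χ² = Σ z_i² with z_i = R₁₂ᵢ/ε_i; dof equals the number of records in the
evaluated subset (not reduced by the fitted-parameter count, matching the
convention of quoting χ² per cohort subset); the model is "accepted" when
the upper-tail probability exceeds 0.05. Standardised group width is
1.96 × SD(z), the same convention as the raw width, so the two are
directly comparable (≈1.96 when the model explains the data).

## Synthetic cohorts

The generator realises the uncertainty model exactly, so that every
downstream stage can be tested without external data. Per patient × ROI
kind it draws N ~ log-uniform(100, 10000) (parenchyma ROIs fixed at 150
voxels), D_true ~ U(76, 198) and an observed histogram width
w ~ U(10, 60), then per session

    D_obs = D_true (1 + g_sys) + e,
    g_sys ~ N(0, ε_sys / (100 √2)),      e ~ N(0, √((β² w² + σ_fix²)/N)),

so R₁₂ has, to first order, exactly the model variance. Two deliberate
design points:

* the session-level systematic error uses SD ε_sys/(100√2) so that its
  pairwise contribution to R₁₂ has SD ε_sys, matching its quadrature role;
* σ_fix is realised as an extra dispersion of the *mean* (σ_fix/√N), not
  folded into the reported histogram width. Folding it into w would make
  the data variance β²(w_bio² + σ_fix²)/N, which the model can absorb
  entirely into its β term — σ_fix would be unidentifiable and always
  fitted at zero. The adopted form keeps all three parameters separately
  identifiable (β through the w²/N spread, σ_fix through the 1/N floor,
  ε_sys through the size-independent remainder).

Reported widths carry the sampling jitter of a sample SD (relative SD
1/√(2N)). Motion is a one-sided multiplicative bias, U(5%, 30%), applied
to one randomly chosen session of a Bernoulli(0.25)-selected subset of
patients, with that session flagged; it is intentionally outside the
model. Default cohort geometry mirrors the study: 20 patients, four ROI
kinds, 25% motion.

What the generator does **not** emulate: re-delineation variability
(sessions share N, so synthetic ΔVOL% is degenerate at 0), real spatial
noise correlation (β is imposed, not emergent), non-Gaussian ADC
distributions, registration error, and the physics of respiratory motion.
Passing tests therefore demonstrate internal consistency of the
estimation machinery under the model's own assumptions, not its adequacy
for any particular scanner or anatomy.

A voxel-level phantom (spherical lesion, mono-exponential decay at
b = 100/500/900 s/mm², Rician magnitude noise) exercises the ADC-mapping
path end to end, including NIfTI round-trips.

## ADC mapping and the noise floor

Voxel ADC is the negated OLS slope of ln(signal) against b; the default
b-set is {100, 500, 900} s/mm² (configurable — some scanners also acquire
b = 0). Unweighted log-linear OLS is the minimal reading of a
"mono-exponential fit"; a voxel is invalid (masked, not raised) when fewer
than two b-values have positive corrected signal or the slope is
non-finite. ROI summaries use the arithmetic mean and the sample SD
(N−1) of valid masked voxels. Partial-volume handling (e.g. dropping
first/last tumour slices) is the mask producer's responsibility.

Magnitude noise is corrected by quadrature subtraction,
√(max(S² − 2σ², floor)), the first-moment-consistent correction for
single-coil Rician data (E[M²] = A² + 2σ²); the floor is a small clamp
(5% of σ, capped by the signal itself, so the output never exceeds the
input and is the identity at σ = 0). A measured limitation, documented
here deliberately: the subtraction is exact in the *second* moment, so it
removes the noise-floor bias of ensemble/ROI-level signal (root mean
power) — per-voxel log-domain fitting of corrected signal is *not*
improved at moderate SNR, where raw log-magnitude fitting already enjoys
a first-order Rician bias cancellation. The tests assert exactly these
verified properties; for low-SNR per-voxel work a full Rician likelihood
fit would be required (out of scope).

## Problem sizes used in the automated checks

Parameter recovery uses 200 replicate cohorts of 60 tumour ROIs
(20 patients × 3 tumour ROI kinds, no motion) at the published best-fit
truth (β, σ_fix, ε_sys) = (4.87, 69.35, 2.65); the pass condition is
median relative bias below 10% per parameter. Calibration uses 1000
replicates (mean χ²/dof within 1 ± 0.1; pooled 1.96 × SD(z) within
[1.7, 2.2]). The motion test pools five 80-ROI cohorts at 25% motion and
requires rank-sum p < 0.01 for motion |z| exceeding clean |z|. These sizes
give stable Monte-Carlo summaries for the quantities asserted.

## Known limitations

* The exact published fit (β = 4.87, σ_fix = 69.35, ε_sys = 2.65,
  χ² = 11.33 with 15 dof, CoV = 5.3%, widths 21.1% → 2.7%) requires
  per-ROI histogram widths and the 2D/parenchyma measurements, which were
  not published; the packaged per-patient table supports group statistics
  only (its CoV and ΔVOL% statistics do reproduce the printed values).
  A freely linked archival dataset can be ingested through the ordinary
  ROI-table reader by anyone who fetches it.
* dof conventions, the 1.96×SD width and ddof = 0 are documented choices
  matched to the printed numbers, not universal conventions.
* The MLE is slightly biased low at n = 60 (visible in the recovery
  medians); no small-sample correction is applied.
* Multi-coil (non-central χ) noise, IVIM/kurtosis decay, motion
  correction and registration are out of scope.
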