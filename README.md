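# adcrepeat

Test–retest repeatability and data-driven measurement-uncertainty
modelling for ADC (apparent diffusion coefficient) imaging biomarkers.

Mean ADC over a tumour ROI is widely used to detect early treatment
response, but whether an observed test–retest change is meaningful depends
on the statistical uncertainty of *that* measurement — which varies
strongly with ROI size and ADC heterogeneity. `adcrepeat` is for imaging
scientists and trial methodologists who need to (a) quantify per-lesion
repeatability, (b) model its predictable sources of error, and (c) decide
how large a change in an individual tumour is significant.

## The model

Repeatability of a pair of test/retest mean ADC values D₁, D₂ is the
symmetric percentage change

```
R₁₂ = 2 (D₁ − D₂) / (D₁ + D₂) × 100 .
```

First-order error propagation turns per-session mean-ADC errors
σ_D1, σ_D2 into an uncertainty on R₁₂:

```
ε(σ_D1, σ_D2) = 400 √(D₁² σ_D2² + D₂² σ_D1²) / (D₁ + D₂)² ,
```

and three error sources combine in quadrature into the predicted
uncertainty of each observed pair:

```
ε²_R12 = β² ε(w₁/√N₁, w₂/√N₂)² + ε(σ_fix/√N₁, σ_fix/√N₂)² + ε²_sys
```

where w is the ROI's ADC histogram SD, N its voxel count, β a
dimensionless inflation of the histogram-derived standard error, σ_fix a
fixed per-voxel fitting dispersion and ε_sys the irreducible systematic
(scanner) error in percent. The parameters are fitted by maximum
likelihood to observed repeatability records (motion-corrupted records
excluded), checked by χ² goodness of fit, and used to standardise each
R₁₂ to z = R₁₂/ε_R12 — approximately N(0, 1) when the model holds — and
to build look-up charts of expected uncertainty versus ROI size and
histogram width. See `docs/methods.md` for the full account.

The package also provides voxel-wise mono-exponential ADC mapping from
multi-b-value magnitude DWI (b = 100/500/900 s/mm² by default) with
Rician noise-floor correction, NIfTI phantom I/O, and a synthetic
test–retest cohort generator that realises the uncertainty model exactly,
so the whole pipeline is testable without patient data.

## Worked example

Group statistics of the packaged 20-patient liver-metastasis summary
table (3D whole-tumour ROIs, averages of two baselines):

```
$ adcrepeat table2
{
  "n_patients": 20,
  "n_motion": 5,
  "delta_vol_pct": {
    "n": 20,
    "mean": 0.6045,
    "sd": 8.2180,
    "ci_width_95": 16.1074
  },
  ...
  "avg_mean_adc": 108.4,
  "adc_range": [76.0, 198.0]
}
```

Tumour volumes were re-outlined to within a mean 0.6% (SD 8.2%) between
visits, so a volume change beyond ±16.1% (1.96 × SD) would be
significant; 5 of 20 datasets show visible motion. The within-subject CoV
recovered from this table is 5.29%.

Full pipeline on a synthetic study-like cohort (80 ROIs, 25% motion):

```
$ adcrepeat report --seed 42 --out out/
{
  "raw_width_95": 34.59,
  "standardised_width_95": 2.93,
  "cov_pct": 11.10,
  "outdir": "out/"
}
```

The 95% confidence-bound width of raw ΔADC% across the cohort is 34.6%
— dominated by small ROIs and motion — but after standardising each
measurement to its modelled uncertainty the width is 2.93 on the z scale,
close to the ideal 1.96; the excess is carried by the motion-corrupted
records, which stand out as outliers regardless of lesion size. `out/`
contains the records CSV, fitted parameters, goodness-of-fit JSON,
figures with their plotted numbers as CSV, the look-up grid and a run
manifest.

Per-measurement uncertainty at the fitted parameters
(β = 4.87, σ_fix = 69.35, ε_sys = 2.65, D = 109):

| N voxels | histogram SD | ε_R12 |
|---------:|-------------:|------:|
|      150 |           10 |  9.4% |
|      150 |           50 | 27.0% |
|     2000 |           10 |  3.6% |
|     2000 |           50 |  7.8% |
|    10000 |           50 |  4.2% |

A 25% post-treatment ΔADC% in a 150-voxel, SD-50 lesion is within
measurement noise; the same change at 2000 voxels (22.5 cm³ — where the
size benefit begins to plateau) is highly significant.

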