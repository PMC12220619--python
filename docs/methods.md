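# Methods

## The statistic

The package monitors the age structure of wild mosquito cohorts through the
**cohort spectra outlier fraction**

    f = (Σ spectra outlier points) / (Σ spectra points)

computed from shortwave-infrared (SWIR) absorbance scans of the cuticle.
The procedure per cohort (one species × collection-day class, treatment
cycles pooled):

1. **SNV correction.** Each scan (228 absorbance points at 3.5 nm
   resolution) is standardised to mean 0, SD 1 — the Standard Normal
   Variate transform — removing per-scan multiplicative and additive
   scatter. The SD uses the sample (n−1) denominator by default; a
   population-SD flag exists because common SNV practice varies. f is
   invariant to this choice (the fences below rescale with the data), but
   intermediate values are not.
2. **Tukey fences per wavelength.** Over the cohort's scans × wavelengths
   matrix, quartiles are computed independently at each wavelength and
   fences set at Q1 − k·IQR and Q3 + k·IQR with k = 1.5. Quartiles use
   linear interpolation between order statistics (the mainstream
   spreadsheet convention, matching the tooling the field analysis used);
   Tukey hinges are available as an alternative because f is sensitive to
   the estimator at small cohort sizes. Cohorts below 4 scans are
   rejected — quartiles from fewer rows are not meaningful.
3. **Counting.** A matrix cell is an outlier point iff it lies strictly
   outside its wavelength's fences; a point exactly on a fence is not an
   outlier. A relative numerical guard of 1e−12 treats values within
   floating-point jitter of a fence as on it, so cohorts of affinely
   identical scans (which SNV collapses to one row up to ~1e−16 rounding)
   give f = 0 exactly.
4. **f** = outlier points / (n_scans × 228). Each scan replicate is its
   own matrix row (the study scanned every specimen twice and kept both
   records: 3100 specimens × 2 scans × 228 points = 1,413,600 records);
   a per-specimen averaging mode is available but not the default.

A rise in f across an adulticide treatment indicates a younger, more
age-heterogeneous cohort (new recruits beside surviving older
individuals); a fall indicates recruitment of older mosquitoes or poor
control.

**Pooling matters:** combined cohorts (POST d1+d2, or cycles within a day
class) recompute the fences on the pooled matrix. Pooled f is *not* any
weighted mean of sub-cohort f values, because pooling shifts the fences;
the published pooled values confirm this and the tests exercise it on
constructed examples.

## Measurement tolerance

Differences in f smaller than the scanning measurement tolerance τ are
reported as "no change". The study estimated τ = 0.0008 from two scanning
trials of aspirin tablets; that constant is packaged as the default. The
published reduction from trials to τ is not spelled out (the stated
"four significant digits" rounding is not self-consistent for 0.0008), so
`measurement_tolerance` implements a documented stand-in: the maximum
pairwise |Δf| across trials, rounded to 4 decimal places — which for two
trials is simply |f₁ − f₂|.

Gating: |f_later − f_earlier| ≤ τ ⇒ direction "no change" and the relative
difference (the plain ratio f_later/f_earlier, which is what the published
ratios reproduce) is reported as 0.

## Trend groups

Species are classified from the abundance triple (PRE, POST d1, POST d2
trap counts) and f triple by a decision tree that formalises the narrative
group descriptions, with "offsets abundance reduction" operationalised as
raw POST d2 count ≥ PRE count:

- **A**: abundance down on d1, f up beyond τ on d1 (young recruits), f back
  down beyond τ on d2 with abundance recovered (older recruits restore
  counts);
- **B**: as A but abundance not recovered by d2;
- **C**: no f rise on d1 (|Δf| ≤ τ), f up beyond τ on d2, abundance not
  recovered;
- **D**: everything else.

The tree reproduces all 11 published assignments at τ = 0.0008. Because it
is an interpretation, the raw predicates are exported next to the group
label so assignments can be re-derived under other rules.

## Regression series

All fits are simple OLS with intercept, two-sided t test on the slope,
df = n − 2, no multiple-testing correction (none was applied in the field
analysis), missing pairs dropped pairwise. The predictor construction per
response block was fixed by reproducing the published coefficients:

- per-day f ~ day-matched abundance and number scanned, plus preservation
  months, RH, temperature;
- actual differences in f ~ the corresponding day-to-day *differences* in
  counts, plus the static covariates;
- relative differences (gated ratios) ~ the corresponding count *ratios*,
  plus the static covariates;
- maximum flight distance ~ the four difference/ratio responses, with the
  two species lacking a published dispersal range dropped (n = 9, so
  df = 7; the published table states df = 8, which is inconsistent with
  n − 2 and not reproduced).

Printed ratios were computed from unrounded f upstream, so recomputing
them from the 4-decimal published f table shifts two cells by one unit in
the last digit (19.8 → 19.7, 6.4 → 6.3); slopes built on ratios differ
correspondingly in the third decimal.

## Synthetic data generator

No spectral model of SWIR cuticle aging is published, so the generator is
an explicit stand-in built from the simplest mechanism that produces the
behaviour the statistic relies on. One scan of a specimen of age *a*:

    spectrum(λ) = scale · [baseline(λ) + amplitude(a)·drift(λ)
                           + water peaks] + offset + noise(λ)

- `baseline`: smooth sloping curve; water O–H bands as Gaussians at
  1210 nm and 1450 nm;
- `drift`: one fixed unit-norm shape, not collinear with the baseline;
- `amplitude(a) = A_max(1 − e^(−a/τ_age))`, A_max = 0.5 absorbance units,
  τ_age = 5 d: spectra change rapidly over the first days of adult life
  and saturate in old age;
- scatter: per-scan scale U(0.7, 1.3) and offset U(−0.1, 0.1), exactly
  what SNV removes;
- noise: per-point detector noise generated in the transmitted-intensity
  domain and propagated through the log
  (A′ = A − log10(1 + ε), ε ~ N(0, ln10·σ), σ = 0.002 default), Gaussian
  at small σ with the right-skewed tail of real absorbance noise at
  large σ. Replicate scans share the specimen's age but draw independent
  scatter and noise.

Cohort age structures: "young mixed" = 90% at 2.0 ± 0.5 d plus a 10%
older remnant at 12 ± 1.5 d; "old homogeneous" = 15 ± 1.5 d; "settled"
(default pre-treatment) = 12 ± 3 d. A treatment study kills old
(≥ 7 d) individuals with probability 0.9 and young with 0.1, adds a
recruit pulse of 0.8 × cohort size at 1 ± 0.5 d, and samples the POST d1
and d2 cohorts from the surviving+recruited pool with ages advanced 1 and
2 days. At these effect sizes, with 50 specimens per cohort:

- young-mixed cohorts give higher f than old-homogeneous ones in ≥ 90 of
  100 seeded replicates (the mechanism: the older minority's saturated
  drift amplitude lies beyond fences set by the tight young majority);
- the kill-old/recruit-young treatment raises pooled post-treatment f
  over PRE f in ≥ 90 of 100 replicates;
- a kill-young/recruit-old treatment lowers it in the clear majority.

These rates collapse if the older minority exceeds roughly a quarter of a
cohort, because the upper quartile then moves into the minority and the
fences widen — a real property of quartile fences, not an implementation
artifact.

**What the generator does not emulate:** biophysically accurate cuticle
spectra, desiccation/preservation-time effects (a known confounder of the
field data, deliberately absent here), species differences beyond the
label, diet/infection effects, and trap-sampling biases. Passing synthetic
tests therefore demonstrates that the pipeline recovers planted
age-structure signals of plausible shape and size — not that field spectra
carry signals of that size.

**A scale-invariance caveat found during development:** because SNV
standardises every scan and the fences are re-estimated from the data,
f — and hence the synthetic standard-trial tolerance — is nearly invariant
to a pure rescaling of the noise level. The tolerance of the simulated
aspirin standard is therefore 0 at zero noise and positive, reproducible
but roughly noise-level-independent otherwise; it should not be read as a
noise meter.

## Problem sizes and numerics

Tests and the acceptance script use 30–50 specimens per synthetic cohort
and 100-replicate success rates, chosen to estimate the orderings stably;
the full-size record-accounting check generates the study-scale 6200 scans
once. All randomness flows from a single integer seed through one
generator. CSV round trips use `%.17g` formatting and round-trip float
parsing, so written spectra re-read bit-identically. Reporting rounds f to
4 decimals, actual differences to 4, ratios to 1, matching the published
precision; all internal arithmetic is full precision.
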