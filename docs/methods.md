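# Methods

This note documents the statistical model behind `momscreen`, the choices
made where the published analysis left the design open, and what the
synthetic cohort generator does and does not emulate.

## Screening model

### MoM normalization

Every marker — five plasma cell-free RNAs, cervical length (cm) and mean
arterial pressure (mmHg) — is standardized as a multiple of the median
(MoM): the raw value divided by the median expected in unaffected
pregnancies at the subject's own covariates. Expected medians are fit on the
non-case group only. For each marker, log10 expression is regressed on
gestational age at sampling (days) and maternal weight; if neither slope is
significant (two-tailed t-test, α = 0.05, configurable) the overall non-case
median is used (CONSTANT form), otherwise the median function is
`10^(a + b·days + c·w)` refit with only the significant terms (LOG_LINEAR
form). Least squares on log10 values estimates the geometric mean, which
equals the median under log-normality — this reproduces the published
`10^(linear)` footnote form, and makes the non-case median MoM exactly 1.00
for the CONSTANT form (sample medians use midpoint interpolation, so the
unity invariant is exact up to floating-point round-off for even group
sizes).

The published median fixtures are shipped in
`momscreen/data/median_models.yaml`: constants for PSME2 (0.85), NAMPT
(2.34), APOA1 (0.16) and APOA4 (2.44); the Let-7g log-linear model
`10^(−0.515 + 0.0106·days − 0.232·w)`; and linear weight models for CL
(3.14 + 0.00287·kg) and MAP (75.4 + 0.0409·kg). The weight term `w` in the
Let-7g model is dimensionally ambiguous as printed; a coefficient of −0.232
per kilogram would drive the median to ~10^−17 at 80 kg, so `w` is taken as
log10(kg) by default (at 80 kg the median is then ≈ 2.6, a plausible assay
scale). The transform is configurable (`weight_transform="identity"`).

### Univariate screens

Case and non-case log10 MoM distributions are compared with the Wilcoxon
rank-sum test: exact enumeration when the smaller group has ≤ 8 observations
and the pooled sample is tie-free, otherwise the normal approximation with
continuity and tie corrections. RNAs are tested two-tailed; CL and MAP
one-tailed in their clinically expected directions (cases: shorter cervix,
higher pressure). Categorical characteristics use the Pearson chi-square
test without continuity correction. No multiple-testing adjustment is
applied across the five-marker panel, matching the source analysis; reports
carry raw p-values. Marker–CL interactions use the Pearson correlation
(rank correlation would be the natural alternative; the implementation
computes Pearson because the source reports plain `r`).

### Risk models

Risk is logistic: linear predictor `x = β₀ + Σ βᵢ zᵢ` over log10 marker MoMs
and clinical terms, odds `y = e^x`, probability `p = y/(1 + y)`. (The source
text prints the transform as `p = y/(1 − y)`, which exceeds 1 for x > 0;
this is read as a sign typo for the standard logistic form.) Clinical
encodings follow the published equations: an indicator for race other than
non-Hispanic Black; a smoking indicator; the earliest gestation of a prior
preterm birth in weeks, with 40 recorded when there was none; and parity
entering the preeclampsia models through nulliparous and parity-1–2
indicators with parity ≥ 3 as the reference level (the published equation
lists offsets only for the first two levels, so the third is taken as 0).

Models are fit by maximum likelihood (Newton/IRLS, tolerance 1e-8 on the
coefficient step, 100 iterations). Quasi-complete separation — plausible
here because the early-onset preeclampsia stratum can contain zero parity-1–2
cases — is flagged when any standardized coefficient exceeds 15 in
magnitude, or when the MLE fails outright; a lightly ridge-penalized IRLS
fit (λ = 1e-4 on slopes, intercept unpenalized) then replaces the diverging
estimate. The ridge fallback is never applied to the published fixed
equations, which are exact arithmetic.

**Missingness variants.** NAMPT and APOA1 occasionally fall below the qPCR
detection limit, and CL/MAP were measured only in subsets. For every
marker-availability pattern observed in the training data, a sub-equation is
fit on the markers available in that pattern (clinical covariates always
retained); scoring dispatches each subject to the variant matching the
largest available subset of their markers. Patterns with fewer than 5
complete-data cases fall back to the next-smaller predictor sets, down to a
covariates-only equation.

### Performance

AUC is computed as the Mann–Whitney probability (ties get half credit) with
a 95% CI from the DeLong placement-variance estimator, truncated to (0, 1);
Hanley–McNeil is available via `ci_method`. Detection rates at fixed
false-positive rates f ∈ {10%, 20%, 30%} threshold the risk probabilities at
the (1−f) empirical percentile of the control scores (linear interpolation
between order statistics; "positive" is strictly above the threshold), so
the observed control exceedance never overshoots f by more than one
control's worth of granularity. The interpolated-percentile convention is a
design choice — nearest-rank is the main alternative and differs by at most
one control rank. Controls are always the subjects with neither preterm
birth nor preeclampsia, mirroring the source design.

## Synthetic cohort generator

The generator reproduces the *shape* of the original cohort: outcome
prevalences (sPTB < 37 w 25.3% of which ≤ 32 w is 10.4% of the cohort;
preeclampsia 7.6% with EOP 2.1%), covariate frequencies (85% non-Hispanic
Black, 27.3% smokers, parity 0 / 1–2 / 3+ at 17/57/26%), prior-PTB rates
conditional on outcome (83% / 79% / 43% for ≤ 32 w cases, < 37 w cases and
others), and the distribution of the earliest prior-PTB gestation (≤ 32 w
with probability 0.92/0.74/0.65 by group, uniform within the band, 40
sentinel otherwise). Each marker's log10 MoM is drawn normal around the
log10 of its group's published median MoM; raw values are reconstructed by
multiplying by the published median model at the subject's covariates.
Maternal weight is N(80, 18²) kg truncated to [40, 180]; sampling gestation
is uniform over days 112–146. The lowest 5% of NAMPT and 2% of APOA1 raw
values are censored below detection; CL is present for 53% of subjects and
MAP for 90%, matching the reported subset sizes. All draws flow from a
single seed.

**Free parameters.** The source reports group median MoMs but no spread, so
the log10-MoM standard deviations are assumptions: 0.35 for the RNAs, 0.10
for CL, 0.03 for MAP (order-of-magnitude plausible for qPCR fold-change
panels, sonographic CL, and blood pressure respectively; all configurable).
Markers are drawn independently within subject — real RNA panels are
correlated. These two simplifications matter jointly: with independent
markers at sd 0.35, the two-RNA model for ≤ 32 weeks separates synthetic
cases and controls almost completely (AUC ≈ 0.99), well above the clinical
AUC of 0.76. The published headline AUCs (0.76, 0.83, 0.89, 0.96) therefore
are context, not reproduction targets: they depend on the unavailable cohort
and on unreported variances and correlations. What the test suite verifies
instead is the machinery — exact agreement of the AUC with exhaustive pair
counting, the DR-at-FPR construction guarantees, coefficient recovery when
cohorts are simulated from the published equations, and type-I-error
calibration of the rank-sum and chi-square tests. The observed synthetic
AUC of the two-RNA model is reported (as a test warning) for inspection but
is deliberately non-gating.

Other aspects of the real study the generator does not emulate: biweekly
longitudinal sampling, umbilical-cord samples, progesterone-treated
subjects, and any covariate–marker correlation beyond the covariate terms of
the median models.

## Numerical and scale choices

- Monte-Carlo problem sizes: generator calibration is checked at n = 20,000
  subjects (median MoMs within ±10% per group, covariate rates within 3
  standard errors); coefficient recovery at n = 5,000; type-I error at 2,000
  replicates. These sizes keep each check's sampling error well inside its
  tolerance while the whole suite runs in seconds.
- The recovery simulation draws marker log10 MoMs with sd 0.5, other-race
  at 15%, prior PTB at 50% with earliest gestation uniform on [16, 36]
  weeks — chosen so the event rate under the published ≤ 32 w equation
  (~20%) identifies every coefficient within ±15% at n = 5,000.
- ΔΔCT preamplification offsets are not modelled: constant cycle offsets
  cancel in the double difference and again in MoM normalization.
- Degenerate inputs: constant reference values or constant covariates force
  the CONSTANT median form; a non-positive predicted median is a hard error;
  an all-tied rank-sum comparison returns p = 1 with a warning; constant
  control scores in the DR construction warn and report the case fraction
  above the constant.
- Extreme MoMs are not truncated (some screening programmes cap MoMs at,
  e.g., [0.2, 5]; the source analysis does not mention truncation).

## Known limitations

- The fitted LINEAR median form (used by the CL/MAP fixtures) is applied but
  never estimated; refitting medians for CL/MAP falls back to the published
  fixtures.
- Missingness sub-models are fit on all subjects with the pattern's markers
  available (not only subjects with exactly that pattern), which is the
  larger, more stable training set but assumes missingness is unrelated to
  outcome given the predictors.
- The DeLong CI is asymptotic; for the 6-case EOP stratum it is reported but
  fragile, as in the source analysis.
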