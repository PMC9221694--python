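# momscreen

A mid-trimester screening pipeline for maternal plasma cell-free RNA markers
of spontaneous preterm birth (sPTB) and preeclampsia.

Five plasma cell-free RNAs (*PSME2*, *NAMPT*, *APOA1*, *APOA4*,
*Hsa-Let-7g*), measured by qPCR at 16.0–20.9 weeks' gestation, plus
sonographic cervical length (CL) and mean arterial pressure (MAP), are
combined with clinical history into logistic risk models for four case
definitions: sPTB/PPROM delivering ≤ 32 weeks, all preterm birth < 37 weeks,
early-onset preeclampsia (< 34 weeks, EOP), and all preeclampsia.
`momscreen` implements the full analysis as a reusable, tested library with a
command-line front end, together with a synthetic cohort generator that
emulates the statistical structure of the original single-centre cohort
(n = 289) so every stage can be exercised end-to-end without patient data.

## The method

1. **Expression.** qPCR threshold cycles are converted to relative expression
   with the comparative-CT method, `2^(−ΔΔCT)`, where
   `ΔΔCT = (CT_marker − CT_normalizer) − ΔCT_reference`. Reactions at or
   beyond the cycle cutoff (default 40) are flagged below detection.
2. **MoM normalization.** Each measurement is divided by the median expected
   in unaffected pregnancies at the subject's covariates — either the overall
   non-case median, or a regression median `10^(a + b·days + c·w)` when
   log10 expression is associated with gestational age or maternal weight
   (two-tailed t-test at α = 0.05). The published median models (e.g.
   PSME2 = 0.85; CL = 3.14 + 0.00287·kg) ship as packaged fixtures.
3. **Univariate screens.** Case vs non-case log10 MoMs are compared with the
   Wilcoxon rank-sum test (two-tailed for RNAs; one-tailed for CL and MAP in
   their expected directions); categorical characteristics with the Pearson
   chi-square test. Markers with p < α enter the risk models.
4. **Risk models.** Logistic regression on log10 MoMs and clinical terms:
   `x = β₀ + Σ βᵢ·zᵢ`, odds `y = e^x`, risk `p = y/(1 + y)`. The four
   published best-fit equations are available as fixtures; when a marker is
   below detection, a sub-equation fit on the remaining predictors scores
   that subject (missingness-pattern variants).
5. **Performance.** AUC as the Mann–Whitney probability with a DeLong 95% CI,
   and detection rates (DR) at fixed false-positive rates of 10/20/30%, with
   thresholds at the 90th/80th/70th percentiles of the control risk scores.

## Worked example

Simulate a cohort at the study size and run the full analysis with the
published equations and median fixtures:

```bash
momscreen simulate --n 289 --seed 1 --out cohort.csv
momscreen run --input cohort.csv --outdir report \
    --equation-mode published --median-mode fixtures
```

`report/association_SPTB_LE32.csv` then contains the univariate screen for
the ≤ 32 weeks case definition (medians are MoMs; compare the synthetic case
medians with the generator's targets of 4.09 for PSME2 and 8.84 for Let-7g):

```
marker,case_median_mom,noncase_median_mom,n_case,n_noncase,tails,p_value
PSME2,4.06,0.91,28,190,2,2.6044905856179848e-11
LET7G,8.23,0.93,28,190,2,1.1280065875357512e-15
CL_CM,0.68,0.99,13,101,1,2.400309486701564e-05
...
```

and `report/performance.csv` the screening summary, one row per outcome:

```
outcome,model,auc,auc_ci_lo,auc_ci_hi,n_cases,n_controls,dr_at_fpr_10,dr_at_fpr_20,dr_at_fpr_30
SPTB_LE32,"PSME2, LET7G, other_race, earliest_prior_ptb_weeks",0.93,0.893,0.967,28,190,71.4,85.7,100.0
PTB_LT37,"PSME2, other_race, smoker, earliest_prior_ptb_weeks",0.762,0.694,0.83,72,190,47.2,61.1,68.1
EOP_LT34,"NAMPT, APOA1, nulliparous, parity_1_2",0.662,0.54,0.783,8,177,12.5,25.0,25.0
PREECLAMPSIA,"NAMPT, MAP_MMHG, nulliparous, parity_1_2",0.717,0.614,0.82,24,169,25.0,37.5,66.7
```

Reading the first row: on this synthetic cohort the published ≤ 32 weeks
equation separates the 28 cases from the 190 non-case controls with AUC 0.93
(95% CI 0.89–0.97) and detects 71% of cases at a 10% false-positive rate.
Absolute synthetic AUCs depend on the generator's assumed marker spread (see
`docs/methods.md`); they are not estimates of the clinical values.
`momscreen run` with `--equation-mode fit` instead refits the models on the
input cohort, with missingness variants, and `run.log` records the seed,
versions, chosen variants and any separation warnings. The stage subcommands
`normalize`, `associate`, `fit`, `score` and `evaluate` expose the individual
steps over the same CSV schema.

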