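# Published best-fit logistic risk equations. The linear predictor is
#   x = intercept + sum(coef * transformed predictor)
# with transforms: log10_mom (log10 of the marker MoM), indicator (0/1
# clinical flag), linear (continuous covariate). Risk p = e^x / (1 + e^x).
SPTB_LE32:
  outcome: SPTB_LE32
  intercept: 1.4677
  terms:
    - {name: PSME2, transform: log10_mom, coef: 0.5732}
    - {name: LET7G, transform: log10_mom, coef: 0.8268}
    - {name: other_race, transform: indicator, coef: -1.8931}
    - {name: earliest_prior_ptb_weeks, transform: linear, coef: -0.1119}
PTB_LT37:
  outcome: PTB_LT37
  intercept: 2.9733
  terms:
    - {name: PSME2, transform: log10_mom, coef: 0.1964}
    - {name: other_race, transform: indicator, coef: -1.3671}
    - {name: smoker, transform: indicator, coef: -0.8335}
    - {name: earliest_prior_ptb_weeks, transform: linear, coef: -0.1111}
EOP_LT34:
  outcome: EOP_LT34
  intercept: -7.900
  terms:
    - {name: NAMPT, transform: log10_mom, coef: 2.2726}
    - {name: APOA1, transform: log10_mom, coef: 0.8267}
    - {name: nulliparous, transform: indicator, coef: 3.6091}
    - {name: parity_1_2, transform: indicator, coef: -7.9772}
PE_ALL:
  outcome: PREECLAMPSIA
  intercept: -2.1134
  terms:
    - {name: NAMPT, transform: log10_mom, coef: 1.0161}
    - {name: MAP_MMHG, transform: log10_mom, coef: 21.5283}
    - {name: nulliparous, transform: indicator, coef: 0.8873}
    - {name: parity_1_2, transform: indicator, coef: -0.8217}
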