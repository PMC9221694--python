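# Published expected-median models for each marker, fit on unaffected
# pregnancies of the source cohort. Forms:
#   CONSTANT:   median = intercept
#   LINEAR:     median = intercept + ga_days_coef*days + weight_coef*kg
#   LOG_LINEAR: median = 10**(intercept + ga_days_coef*days + weight_coef*w)
#               where w = log10(kg) or kg per weight_transform
PSME2:
  form: CONSTANT
  intercept: 0.85
NAMPT:
  form: CONSTANT
  intercept: 2.34
APOA1:
  form: CONSTANT
  intercept: 0.16
APOA4:
  form: CONSTANT
  intercept: 2.44
LET7G:
  form: LOG_LINEAR
  intercept: -0.515
  ga_days_coef: 0.0106
  weight_coef: -0.232
  weight_transform: log10
CL_CM:
  form: LINEAR
  intercept: 3.14
  weight_coef: 0.00287
MAP_MMHG:
  form: LINEAR
  intercept: 75.4
  weight_coef: 0.0409
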