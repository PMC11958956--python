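# Phenotypic-age coefficient set, version 1.
#
# Linear predictor xb = intercept + sum(coef_j * biomarker_j) + coef_age * age.
# Units are bound to the coefficients (Levine convention) and must not change:
#   albumin          g/L
#   creatinine       umol/L
#   glucose          mmol/L
#   ln_crp           ln(mg/dL)
#   lymphocyte_pct   %
#   mcv              fL
#   rdw              %
#   alp              U/L
#   wbc              1000 cells/uL
#   age              years
# Mortality score: 1 - exp(-gompertz_a * exp(xb) / gompertz_b)
# Phenotypic age:  pa_c1 + ln(pa_c2 * ln(1 - mortality_score)) / pa_c3
# Note: pa_c1 is carried here as the printed 141.50 (the original Levine
# publication gives 141.50225); the difference is a constant 0.002-year shift.
intercept = -19.907
albumin = -0.0336
creatinine = 0.0095
glucose = 0.1953
ln_crp = 0.0954
lymphocyte_pct = -0.0120
mcv = 0.0268
rdw = 0.3306
alp = 0.0019
wbc = 0.0554
age = 0.0804
gompertz_a = 1.51714
gompertz_b = 0.0076927
pa_c1 = 141.50
pa_c2 = -0.00553
pa_c3 = 0.09165
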