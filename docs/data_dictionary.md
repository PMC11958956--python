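# Cohort table data dictionary

One row per participant; comma-separated UTF-8 text with a header row and
`.` decimal separator. Columns marked *generated* are produced by
`bioaging_mixtures.synthdata.generate_cohort`; columns marked *derived* are
appended by the clocks / exposure stages.

## Identifiers and design

| column | type | description |
| --- | --- | --- |
| `participant_id` | int | 1-based row identifier |
| `stratum` | int | sampling stratum label (round-robin assignment) |
| `psu` | int | primary sampling unit label within stratum (>= 2 per stratum) |
| `weight` | float | examination weight; positive, scaled to sum to n |

## Demographics and covariates

| column | type | levels / units |
| --- | --- | --- |
| `age` | float | years, uniform on the configured range (default 20-80) |
| `sex` | str | Female, Male |
| `race` | str | NH White, NH Black, Mexican American, Other |
| `pir` | str | poverty-income ratio category: Low, Middle, High |
| `bmi_cat` | str | Normal, Overweight, Obese |
| `marital` | str | Never married, Married/partner, Widowed/Div/Sep |
| `education` | str | College or more, High school, Middle school or lower |
| `home` | str | Owned, Rented |
| `smoke` | str | Never, Former, Now |
| `drinks` | str | Nondrinker, Moderate, Heavy |
| `activity` | str | Active, Inactive, Moderate, Others |
| `cycle` | str | survey cycle: 2005-2006, 2007-2008, 2009-2010 |
| `hypertension`, `dm`, `cvd`, `cancer` | int | 0/1 disease indicators |
| `energy_kcal` | float | daily energy intake, kcal |
| `diet_score` | float | healthy-diet score, 0-100 |

## Clock biomarker panels

Klemera-Doubal panel (`kdm_*`): `kdm_lncrp` (ln mg/dL), `kdm_creatinine`
(serum, mg/dL), `kdm_hba1c` (%), `kdm_albumin` (g/dL), `kdm_totchol`
(mg/dL), `kdm_bun` (mg/dL), `kdm_alp` (U/L), `kdm_sbp` (mmHg).

Phenotypic-age panel (`ph_*`, Levine unit convention): `ph_albumin` (g/L),
`ph_creatinine` (umol/L), `ph_glucose` (mmol/L), `ph_lncrp` (ln mg/dL),
`ph_crp` (mg/dL, = exp(`ph_lncrp`)), `ph_lymphpct` (%), `ph_mcv` (fL),
`ph_rdw` (%), `ph_alp` (U/L), `ph_wbc` (1000 cells/uL).

The two panels are disjoint synthetic columns even where real assays
overlap, so injected effects on one clock never leak into the other.

## Urinary analytes

For each analyte `a` in perchlorate, nitrate, thiocyanate:

| column | type | description |
| --- | --- | --- |
| `urinary_creatinine` | float | urinary creatinine, mg/dL |
| `{a}_conc` | float | measured concentration, ug/L; missing when below LOD |
| `{a}_below_lod` | int | 1 if the value was below the limit of detection |
| `{a}_lod` | float | limit of detection on the concentration scale, ug/L |

## Derived columns (exposure stage)

| column | description |
| --- | --- |
| `{a}_lodimp` | ug/L after LOD/sqrt(2) imputation |
| `{a}_cc` | creatinine-corrected value, ug/g creatinine |
| `{a}_ln` | natural log of `{a}_cc` (main analysis exposure) |
| `{a}_q` | survey-weighted quartile label 1-4 (1 = reference) |
| `{a}_std` | covariate-adjusted standardized value, ug/L (sensitivity path) |
| `{a}_std_ln` | natural log of `{a}_std` |

## Derived columns (clocks stage)

| column | description |
| --- | --- |
| `phenotypic_age` | phenotypic age, years |
| `kdm_biological_age` | Klemera-Doubal biological age, years |

## Ground-truth sidecar

`<cohort>_truth.txt` (key-value text) records the generator seed, every
injected effect (`effect.<analyte>.<outcome>`, years per ln-unit), true
biomarker slopes/intercepts/SDs, analyte log-scale parameters and LODs, the
normalized mixture weights implied by the injected effects, and the weight
dispersion. It round-trips losslessly through
`GroundTruth.to_text` / `from_text`.
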