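# bmirecal

Recalibrate BMI cut-off points for overweight and obesity against a DXA
body-fat reference classification, for populations (young male athletes)
where the generic WHO thresholds of 25 and 30 kg/m² over-call adiposity.

The package implements the full analysis as a tested, reusable pipeline:

1. **Adiposity classification** — subjects are classified by body-fat
   percentage (reference bands: ≥21% overweight, ≥26% obesity) and by BMI
   (WHO or arbitrary cut-offs), with all agreement statistics between the
   two systems: unweighted Cohen's kappa, Pearson chi-squared test of
   independence (no continuity correction), capture / false-positive rates
   and Landis–Koch verbal bands.
2. **Linearity testing** — a residual-CUSUM test with a seeded Monte-Carlo
   permutation null (residuals are permuted and the line refitted, so the
   null respects the least-squares constraints).
3. **Model building** — least-squares polynomial regression of ln(BMI) on
   BF%, degree selected by adjusted R², plain R² reported.
4. **Back-transform validation** — measured BMI regressed on predicted BMI
   (antilog of the fitted polynomial), with an F test of the slope = 1
   restriction, a paired t-test on the mean difference, Pearson correlation
   and a CUSUM linearity check.
5. **Cut-off derivation** — the body-fat thresholds are substituted into the
   fitted model and back-transformed to BMI units; an inverse map from BMI
   to BF% solves the quadratic on its rising branch.
6. **Synthetic cohort generator** — because the original DXA dataset is not
   deposited, a calibrated generator reproduces its statistical structure
   (truncated-gamma BF% distribution, log-quadratic BMI relation, lean /
   fat / bone decomposition, inclusion criteria enforced by redraw). The
   generating coefficients were pre-solved from three anchor conditions;
   `scripts/solve_generating_coeffs.py` reproduces the frozen constants.

## CLI

```sh
recal generate --n 622 --seed 42 --out cohort.csv
recal classify --cohort cohort.csv --bmi-cutoffs 25,30 --bf-bands 21,26 --collapse --out agreement.json
recal fit --cohort cohort.csv --max-degree 3 --cusum-sims 2000 --seed 7 --out model.json
recal validate --cohort cohort.csv --model model.json --out validation.json
recal derive-cutoffs --model model.json --bf-bands 21,26 --out cutoffs.json
recal run --cohort cohort.csv --seed 7 --out report.json   # full pipeline
recal demo --seed 42                                       # synthetic end-to-end
```

Cohort CSV columns: `age,weight_kg,height_cm,bmi,lean_mass_kg,fat_mass_kg,bf_pct`
(UTF-8, dot decimals, header required). `recal run` accepts a YAML config
(keys: `seed`, `alpha`, `cusum_sims`, `max_degree`, `bf_bands`,
`baseline_cutoffs`, `rounding`, `guard`, `collapse`).

## Library example

```python
from bmirecal import (GeneratorConfig, PipelineConfig, generate_cohort,
                      run_full_analysis)

cohort = generate_cohort(GeneratorConfig(n_subjects=622, seed=42))
report = run_full_analysis(cohort, PipelineConfig(seed=42))
print(report.to_dict()["cutoffs"])          # derived BMI cut-offs
print(report.to_dict()["agreement_derived"])  # kappa, chi2, rates
```
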