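# gacalib

Regression-calibration correction of measurement error in gestational age
(GA), with bias-corrected outcome association.

In many low-resource settings GA is measured by fundal height (FH) or
recalled last menstrual period (LMP), both error-prone relative to
ultrasound. When an ultrasound gold standard is available for only part of
a cohort, a calibration model fitted on that validation subset — ordinary
least squares of ultrasound GA on the error-prone measure(s) plus
error-free covariates — yields calibrated GA (the estimated conditional
mean of true GA) for *all* records. Using calibrated GA in a logistic
outcome model removes the attenuation bias that classical measurement
error induces in the log odds ratio; a two-stage bootstrap (recalibrating
in every replicate) propagates the calibration uncertainty into the
standard errors.

The package provides:

- `gacalib.synthetic` — a synthetic-cohort generator with a latent true GA,
  three classically mismeasured GA methods with configurable error SDs and
  partial availability, plausible covariate marginals, and rare binary
  outcomes (neonatal death, low birth weight). Closed-form attenuation and
  correlation oracles make every downstream stage testable.
- `gacalib.calibration` — percentile trimming of the gold standard
  (nearest-rank, inclusive), the calibration OLS fit (FH-only, LMP-only, or
  joint), and prediction of calibrated GA.
- `gacalib.agreement` — Pearson validity, Bland–Altman bias and 95% limits
  of agreement (mean difference ± k·SD, k = 2 by default), bias t-test, and
  preterm (< 37 weeks) classification rates.
- `gacalib.association` — univariable logistic association of GA with a
  binary outcome (continuous or preterm-dichotomized exposure), effect
  conversions (log OR ↔ OR, percent change, OR reduction), and the
  two-stage m-out-of-n bootstrap.
- `gacalib.pipeline` — the full study run (agreement table, association
  table, preterm rates, provenance) and the ultrasound-availability
  sensitivity analysis.

## CLI

```sh
# synthetic cohort
gacalib simulate --out cohort.csv --seed 1 --n 2750

# calibrate FH-based GA against ultrasound (appends ga_calibrated;
# coefficients go to a .model.json sidecar)
gacalib calibrate --cohort cohort.csv --measure fh --out calibrated.csv

# Bland–Altman agreement of a GA column vs ultrasound
gacalib agree --cohort cohort.csv --method ga_fh --reference ga_us --out agree.csv

# association of GA with an outcome (calibrated, bootstrap SE)
gacalib associate --cohort cohort.csv --outcome death --measure lmp \
    --replicates 1000 --sample-size 1500 --seed 7 --out assoc.csv

# full study: agreement + association tables + provenance
gacalib run --cohort cohort.csv --seed 1 --out report/
```

Simulation parameters can be supplied as YAML/JSON via
`gacalib simulate --config config.yaml`; unknown keys are rejected.

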