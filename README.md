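# thyrocal

Dose-error-corrected excess-odds-ratio (EOR) analysis for thyroid
screening cohorts whose individual radiation doses are reconstructed from
a measured thyroid activity and an assigned thyroid mass — a mixture of
**classical** (measurement) and **Berkson** (assignment) lognormal errors.

The package provides, end to end:

- a **synthetic cohort generator** reproducing the statistical structure
  of a post-accident screening study: n = 13,127 subjects, ~45 prevalent
  cases, per-subject activity-error GSDs spanning 1.11–10.13 (mean ~1.35)
  and mass-error GSDs in 1.28–1.41 (mean 1.39), with case status drawn at
  the latent *true* dose;
- **error calibration**: latent lognormal deconvolution of the dose (or
  activity) distribution with per-subject error sizes, and two
  regression-calibration dose corrections (`E[D | measurements]` on the
  dose scale, RC1, and on the activity scale, RC2), both including the
  Berkson mass factor `exp(sigma_delta^2 / 2)`;
- a **logistic EOR risk model**, odds = baseline × (1 + EOR), with six
  nested EOR forms `alpha·D·exp[gamma·D + modifiers]`, maximum-likelihood
  fitting, profile-likelihood confidence intervals and likelihood-ratio
  tests;
- **Monte-Carlo maximum likelihood (MCML)**: the likelihood averaged over
  K posterior dose realizations per subject, propagating dose uncertainty
  into the fit;
- a **pipeline + CLI** (`thyrocal`) writing a reproducible report bundle
  (GSD summary table, 4-treatment × 2-form fit comparison, modifier-model
  table, dose–response curve data with CI band, machine-readable run log).

See `docs/methods.md` for the model, generator design and numerical
details.

## Worked example

```python
from thyrocal import (CohortConfig, generate_cohort, calibrate_cohort,
                      fit_ml, profile_ci, compare_eor)

cfg = CohortConfig()                      # study conditions: n = 13,127
cohort = generate_cohort(cfg, seed=1)
print(f"{len(cohort)} subjects, {int(cohort['y'].sum())} cases")

cal = calibrate_cohort(cohort)
fits = {"naive": fit_ml(cohort, cohort["D_mes"].to_numpy(), "linear"),
        "rc1": fit_ml(cohort, cal["RC1"].doses, "linear"),
        "rc2": fit_ml(cohort, cal["RC2"].doses, "linear")}
print(compare_eor(fits).round(3).to_string(index=False))

lo, hi = profile_ci(fits["rc1"], "alpha")
print(f"RC1 slope 95% CI: ({lo:.2f}, {hi:.2f}) per Gy")
```

Output:

```
13127 subjects, 36 cases
method  alpha  pct_change
 naive  3.461       0.000
   rc1  3.663       5.848
   rc2  3.639       5.153
RC1 slope 95% CI: (1.07, 20.54) per Gy
```

Correcting the dose for its mixed error structure raises the linear EOR
slope by ~5–6% on this cohort — classical error attenuates the naive
slope, and the correction undoes that attenuation. The profile CI is wide
because only a few dozen cases inform the slope.

The same analysis from the shell:

```bash
thyrocal simulate --n 13127 --seed 1 --out cohort.csv
thyrocal calibrate --cohort cohort.csv --out-doses doses.csv
thyrocal fit --cohort cohort.csv --doses doses.csv --dose-column dose_rc1 \
             --form linear --out fit.json
thyrocal report --seed 1 --outdir report/     # full bundle incl. MCML
```

## Layout

```
src/thyrocal/
  growth.py       age-by-sex thyroid mass assignment
  cohort.py       synthetic cohort generator (CohortConfig, generate_cohort)
  calibration.py  latent lognormal fits, RC1/RC2 doses, GSD/QQ summaries
  risk.py         EOR-logistic model, ML fits, profile CIs, LRTs
  mcml.py         posterior dose draws and Monte-Carlo ML
  pipeline.py     report bundle orchestration (RunConfig, run_pipeline)
  cli.py          `thyrocal` command group
```
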