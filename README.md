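# cfsme-costs

Employment discontinuation and its productivity costs in adults with chronic
fatigue syndrome / myalgic encephalopathy (CFS/ME) attending NHS specialist
services. The package is an analysis pipeline for assessment-time patient
records: it scores the standard patient-reported inventories, models which
patients have stopped working, prices the lost work time with a stratified
human-capital estimator, and extrapolates the cohort to annual UK-wide
figures with one-way sensitivity analyses. It is written for health
economists and epidemiologists working with specialist-service registry data.

Because the underlying clinical database is not publicly deposited, the
package ships a synthetic-data generator that emulates the cohort's published
structure (sex mix, age distributions, skewed illness durations, correlated
inventory scores, missingness), so every stage is testable end to end, and a
set of small fixtures holding the published per-stratum inputs so the
headline figures can be recomputed exactly.

## The model

**Outcome.** Employment status is recorded in four categories; "temporarily
discontinued" and "indefinitely discontinued" (both "because of
fatigue-related symptoms") are pooled as the positive outcome against
"currently employed"; "other" and unrecorded statuses are excluded from the
binary comparison.

**Association models.** For covariates x (age per decade, sex, duration of
illness in years, and the Chalder fatigue, SF-36 physical function, HADS
anxiety/depression and pain scores rescaled to 0–10), logistic regression

    logit P(discontinued) = β₀ + βᵀx + centre + year

is fitted by iteratively reweighted least squares on complete cases, each
covariate alone (partially adjusted) and all jointly (fully adjusted), with
Wald 95% CIs exponentiated to odds ratios.

**Costs.** For stratum (a, s) of age band a and sex s, the human-capital loss
is the product

    L_as = N_as · d_as · (m_as / 12) · f_s · y_as

where N is the number of patients, d the fraction who discontinued work, m
the median illness duration in months, y the mean gross annual income, and
f_s the per-sex unemployment fraction — the mean of (duration unemployed /
duration ill) estimated with a t-interval from an external sample of 60
patients.

**Extrapolation.** Each pooled group's annual access rate
r_g = (n_g / years) / catchment × 100,000 is multiplied by the group's UK
population to project annual patients, then by the group's per-person loss to
project annual national cost. Two one-way sensitivity analyses re-run the
whole pipeline at the 95% CI ends of f_s and of the per-stratum discontinued
proportions (Wilson intervals).

## Worked example

```python
from cfsme_costs import cohort, costs, national

summaries = cohort.load_cohort_summary()      # per-stratum N, % stopped, months
economics = cohort.load_economics_table()     # incomes, catchment, UK populations
fractions = {"male": 0.52, "female": 0.47}    # unemployment fractions

table, groups, estimate = national.project_national(summaries, economics, fractions)
print(f"cohort loss GBP {table.total_loss:,.0f} "
      f"({table.loss_per_patient:,.0f} per patient)")
print(f"UK: {estimate.total_patients:,.0f} patients/yr, "
      f"GBP {estimate.total_cost:,.0f}/yr")
```

prints

```
cohort loss GBP 49,223,672 (22,684 per patient)
UK: 4,424 patients/yr, GBP 102,215,180/yr
```

i.e. the 2,170 patients in the cohort had already lost £49.2M of earnings
(£22,684 each) by the time they reached a specialist service, and the
services' catchment access rates imply ~4,400 comparable adults reaching
assessment UK-wide each year, carrying ~£102M of accumulated productivity
loss. The numbered scripts under `analysis/` run the full narrative — cohort
simulation, inventory scoring, the logistic models, the cost table and the
national projection — writing tables to `results/`.

A thin CLI mirrors the scripts: `cfsme-costs simulate|score|analyze|costs|project`.

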