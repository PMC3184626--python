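# Methods

## Scope and data model

The pipeline operates on assessment-time records from specialist CFS/ME
services: demographics (age 18–64 at assessment, sex), centre and year of
assessment, self-reported months between symptom onset and assessment, a
four-category employment status, and item-level responses to the 11-item
Chalder Fatigue Scale (0–3 scoring, total 0–33), the 10-item SF-36
physical-function subscale (items 0/5/10, total 0–100), the two 7-item HADS
subscales (each 0–21) and a 0–100 visual-analogue pain rating. Records are
held in a pandas DataFrame with a fixed schema; age is stratified into six
bands (18–21, 22–29, 30–39, 40–49, 50–59, 60–64) that partition the
eligibility window exactly. The top band is 60–64 everywhere: with
eligibility capped at 64, a "60+" label and "60–64" are coextensive.
"Other" employment status and unrecorded status are kept as distinct states
throughout; they are different facts about a record and are never merged.

## Inventory scoring

A total is the plain item sum when all items are answered. With exactly one
item unanswered the total is pro-rated: sum of answered items × n/(n−1),
which equals imputing the mean of the answered items, then rounded half-up
to the instrument's attainable grid (integers for Chalder/HADS, multiples of
5 for SF-36). With more than one item unanswered the total is missing. The
HADS rule applies per subscale. The pro-rating formula and its rounding are
this package's choice: pro-rating is the standard completion rule for these
instruments and the only linear rule that preserves the scale range. The
VAS is a single rating, so a missing VAS is simply missing.

For regression, scores map linearly onto a common 0–10 range
(score × 10 / scale-max), making the divisors exactly 3.3 (Chalder), 10
(SF-36, VAS) and 2.1 (HADS). The exact-[0,10] map is chosen over an
"approximate" one for determinism.

## Employment models

The outcome pools temporary and indefinite discontinuation against current
employment. Covariates: age as a linear per-decade term using the band
midpoint ÷ 10 (a single odds ratio per decade of age), female sex, illness
duration in years, and the four rescaled inventory scores plus pain.
Centre and assessment year enter every model as unordered categorical
indicators with the alphabetically first level as reference. Fits are
maximum likelihood by IRLS (Newton scoring): convergence when the largest
absolute coefficient change falls below 1e-8, at most 100 iterations;
standard errors from the inverse observed information at the optimum; 95%
CIs are Wald intervals exponentiated to the odds-ratio scale. Probabilities
are clipped at 1e-12 inside the likelihood for numerical safety.
A rank-deficient design raises an error naming the collinear columns
(QR with pivoting); non-convergence or coefficients beyond ±30 —
the signature of complete or quasi-complete separation — set a
non-convergence flag and emit a warning rather than silent output.

Both the partially adjusted (one covariate + centre/year) and fully adjusted
(all eight covariates + centre/year) models are fitted on the single
complete-case set defined by all eight covariates, so their sample sizes
agree. Descriptive comparisons report medians and quartiles (linear
interpolation between order statistics) on available cases per variable;
hypothesis tests are Pearson chi-squared without continuity correction for
categorical variables, the pooled-variance t-test for continuous ones (a
rank-sum test would be the natural alternative where normality is doubted;
the t-test is the default to match the primary analysis), and a
Cochran–Armitage trend test across assessment years applied to the
proportion of patients with above-median illness duration — the trend
construction is a documented package choice, since a trend "on medians" is
not a defined test.

## Cost estimator

Per-stratum loss: L = N · d · (m/12) · f_s · y with N patients, discontinued
fraction d, median illness duration m (months), per-sex unemployment
fraction f_s and mean gross annual income y (GBP/year, 2009 earnings applied
retrospectively without discounting — a deliberate simplification of the
primary analysis, acknowledged as a limitation). All arithmetic is carried
at full floating precision; rounding to whole pounds happens only in report
rendering, because the national-level cells are only reproducible from
unrounded intermediates.

The unemployment fraction is estimated per sex from an external sample of
(illness duration, unemployment duration) pairs. Default: mean of
per-record ratios with an exact t-interval, mean ± t(n−1, 0.975)·SE. A
ratio-of-means variant (mean unemployment ÷ mean illness) is available with
a delta-method SE feeding the same t quantile; the two differ in how they
weight long illnesses, and the mean-of-ratios is the default because the
reported summary is a mean of per-patient fractions. The t-interval is not
truncated at zero: with few, dispersed ratios the lower bound can be
negative, and truncation would understate the uncertainty the sensitivity
analysis propagates. Records with non-positive illness duration are
rejected with a logged diagnostic. Unemployment exceeding illness duration
is permitted: source forms can date work reduction before the recorded
onset.

Per-person losses are reported on pooled groups: 18–21 merges into 22–29
within sex (the sparse youngest band; its population denominators are also
pooled), all other bands stand alone. When stratum summaries are derived
from patient records rather than supplied, N counts all eligible patients,
d is computed among those with any recorded status with "other" in the
denominator (configurable to exclude it — the choice changes d by a few
points and is surfaced rather than hidden), and m uses available cases.

## National extrapolation and sensitivity

Access rate per pooled group: r = (n / years) / catchment × 100,000, with
years = 4 (the study window) by default and configurable. Projected annual
patients = r × UK population / 100,000 (populations supplied in thousands,
converted exactly); projected cost = patients × per-person loss; totals are
sums of unrounded group values. The projection is exactly linear in each
population and each per-person loss.

One-way sensitivity analyses re-run the entire pipeline twice with one
parameter at its interval ends, both sexes moved together: (a) the
unemployment fraction at its per-sex 95% CI bounds; (b) the per-stratum
discontinued proportions at Wilson 95% bounds computed from the stratum
counts — varied jointly across strata by default, with a pooled-per-sex
alternative behind a flag that rescales every stratum by the pooled
proportion's bounds. The Wilson choice is the package's: no method is
derivable for the original, so these results are method-dependent and are
checked only for bracketing the base case, not for exact reproduction.

## Synthetic-data generator

The generator emulates the cohort the analysis assumes, not any real
patient: sex Bernoulli (default 76.9% female); age truncated-normal within
18–64 (means 41.4/38.6 for men/women, SD 11.5); a standard-normal severity
latent z per patient drives all four inventories (items are thresholded
linear functions of z plus item noise) and loads on log illness duration
(log-normal, log-mean 3.68, log-SD 1.15, severity loading 0.35), which
reproduces the longer durations of the discontinued group without an
explicit duration–outcome back-channel beyond the configured coefficient.
Employment status is drawn from the configured logistic model evaluated on
exactly the covariate construction the analysis fits, so recovery and
coverage tests are well-specified by construction. Recorded-status,
"other", and temporary-vs-indefinite splits follow the published marginal
rates (91.8%, 9.1%, 322/998). Missingness is MCAR by default: per
inventory, one item blanked with probability 0.045 (exercising the
pro-rating rule) and two items with probability 0.045 (voiding the total);
duration and VAS missing with probability 0.045 each, giving a
complete-case share near the published ~77%. A config switch makes status
missingness depend on age and fatigue, for probing the complete-case
analysis. The external sample draws each record's unemployment/illness
fraction from Beta(mν, (1−m)ν) with per-sex means 0.52/0.47 and
concentration ν = 2, chosen so the n = 60 t-interval width matches the
reported ±0.12–0.14; fixed sizes 22 men / 38 women.

All randomness comes from a single numpy Generator seeded once per run —
identical (config, seed) reproduce identical records bit-for-bit; vectorised
draws from one stream replace per-record sub-streams with the same
determinism guarantee. Covariates are independent given sex and the
severity latent; real registries have richer joint structure (age × duration
correlation, centre case-mix differences), none of which is modelled. A
passing pipeline on this generator therefore demonstrates correctness of
the estimators under a well-specified data-generating process, and nothing
about robustness to misspecification, informative missingness (unless
switched on), or measurement error in self-reported durations.

## Problem sizes in the tests

Deterministic reproduction checks run on the printed per-stratum fixtures
(12 strata) and complete in milliseconds. The statistical checks use: one
50,000-patient cohort for coefficient recovery within 3 SE; 200 cohorts of
5,000 (SeedSequence-spawned streams, missingness disabled so the check
isolates the estimator) for Wald CI coverage within [92%, 98%]; 1,000
replicate external samples of 60 for fraction-estimator unbiasedness; and
exhaustive enumeration of all 4-item vectors over {0..3, missing} for the
scoring rule. These sizes put Monte Carlo noise well inside the asserted
bands while keeping the whole suite under a minute of simulation time.

## Known limitations

Human-capital valuation assumes lost time is never back-filled; a
friction-cost analysis would give lower figures and is out of scope. The
published odds ratios and group medians of the original cohort are
calibration anchors for the generator, not reproduction targets — the
patient-level data are unpublished, so only their printed summary inputs
are reproducible. No multiple imputation, interactions, or model selection;
no probabilistic sensitivity analysis beyond the two one-way analyses; no
discounting of past earnings to a common price year.
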