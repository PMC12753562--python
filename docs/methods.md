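# Methods

`tmcohort` implements a retrospective, time-matched new-user cohort design
for drug-safety questions on longitudinal claims data, together with a
synthetic claims generator that makes every stage testable against known
ground truth. This note records the models, the defaults and why they were
chosen, the numerical choices, and what the simulations do and do not
establish.

## The design

**Cohort.** Patients enter the universe with a first dyslipidemia diagnosis
(`E78` prefix). The exposed group consists of new users of the study drug:
the index date is the first prescription on or after the first eligible
diagnosis, where "eligible" requires the patient's overall first diagnosis
to fall on or after the drug's launch cutoff. Eight exclusion criteria are
applied at the index date: a full 180-day baseline must be observable; no
fibrate prescription, no VTE diagnosis, and no biliary-atresia/gallstone
diagnosis or cyclosporine/rifampicin prescription during the baseline
window; no study-drug use before the first eligible diagnosis (exposed
only); the observable period must reach the index date (controls only); and
age at index must be at least 20.

**Time-matching.** For an exposed patient whose prescription falls X days
after their first diagnosis, control candidates are all other patients whose
own first diagnosis plus X days is free of study-drug prescriptions over the
inclusive lookback `[index − 180, index]` and who pass the control-role
exclusions at that candidate index. Five controls are drawn uniformly
without replacement per exposed member. Anchoring both groups X days after
their own first diagnosis places them at the same disease age at entry;
this is what removes immortal time bias, and the test suite demonstrates the
bias with a deliberately naive comparator whose controls are anchored at
diagnosis instead.

Window conventions: the baseline window for record-based exclusions and
covariate extraction is `[index − 180, index − 1]` (the index day belongs to
follow-up, and the exposed member's own index prescription must not trip the
fibrate exclusion), while the control lookback for the study drug includes
the index day itself (a control on the drug at index would be exposed).
Control reuse across matched sets is permitted; within a set, sampling is
without replacement. Exposed members are processed in ascending index date
(ties by patient id), so one seed reproduces the cohort exactly. The
uniform-without-replacement draw is implemented by rejection sampling from
the eligible-diagnosis set — distributionally identical to enumerating the
pool, with an exact-enumeration fallback when a pool nearly runs dry; sets
whose pool is smaller than the match ratio are kept partial with a warning
and the realized ratio is reported.

**Follow-up.** ITT follow-up runs from index to the earliest of the outcome
or the end of the observable period, ignoring treatment changes. The
per-protocol scenarios additionally censor the exposed at the end of drug
exposure and at a first other-fibrate prescription, and censor controls at
any first fibrate (including study-drug) prescription. Drug exposure is the
union of per-prescription supply intervals `[date, date + days_supply − 1]`;
consecutive intervals merge into an episode when the uncovered span
(`next_start − current_end − 1`) is at most the gap period, so gap 0 means
seamless refills still merge. A per-protocol scenario censors the exposed
at the end of the episode containing the index prescription plus the grace
period; a later restart after a longer-than-gap break is a new exposure
episode and does not stretch the on-treatment window. Events inside the
grace extension count as on-treatment. The four scenarios use 0, 30, 90 and
180 days for both the gap and the grace period.

**Outcome.** A VTE event requires a VTE diagnosis (`I26`/`I80`/`I82`) plus
a thrombolytic/anticoagulant prescription: outpatient, same patient at the
same facility on the same date; inpatient, both records within the same
hospitalization, dated at the earliest qualifying prescription on or after
the diagnosis (a config switch restricts to strictly after). The earliest
qualifying event inside the follow-up window is the outcome.

**Statistics.** Missing BMI category (six ordinal levels: <18.5, 18.5–25,
25–30, 30–35, 35–40, ≥40) and smoking are multiply imputed by fully
conditional specification: per variable, a statsmodels logistic
(binary) or proportional-odds (ordinal) model is refit on the observed rows
each cycle, a parameter vector is drawn from the approximate posterior
N(β̂, V̂), and missing cells are sampled from the implied predictive
distribution. Predictors are all other covariates plus the event indicator
and log(1 + follow-up days); zero-variance predictors are dropped up front;
chains start from draws of the observed margins and run 10 cycles by
default, with 20 imputations. Non-convergent component models fall back to
a ridge-stabilized fit with a warning.

Propensity scores come from a main-effects logistic regression of exposure
on all covariates (BMI as integer-scored ordinal category), fit per imputed
dataset; near-separation triggers a ridge-stabilized refit. Standardized
mortality ratio weights target the treated population (ATT): weight 1 for
exposed, propensity odds e/(1 − e) for controls. No weight truncation by
default; percentile truncation is available for extreme scores. Balance is
summarized by standardized differences (control minus exposed; binary
variant uses pooled binomial variance), reported unweighted plus the
min/max weighted value across imputations.

The hazard ratio is a weighted Cox partial-likelihood fit with exposure as
the sole covariate — adjustment is carried entirely by the weights. Ties
use the Breslow approximation by default (Efron available); Breslow is the
default of the statistical system the design was originally analyzed with.
The maximizer is a one-parameter Newton iteration written in this package so
that the ties method and the weighted robust (sandwich) variance — built
from weighted score residuals — are explicit; lifelines serves as an
independent cross-check in the tests, and backs the weighted Kaplan–Meier
curves. Per-imputation log hazard ratios and robust variances are pooled by
Rubin's rules (total variance W + (1 + 1/m)B) with the classic Rubin
degrees of freedom, the large-sample limit of the Barnard–Rubin formula —
appropriate because claims cohorts are large. Report tables use pooled
estimates; exported Kaplan–Meier curves come from the first imputed dataset
together with the maximum cross-imputation sup-difference as a consistency
check. Monotone likelihoods (all events in one group) yield a bounded
estimate with a warning; levels without events in subgroup analyses are
flagged inestimable rather than dropped. Subgroup analyses reuse the
full-cohort weights. Person-years use 365.25 days per year.

## The synthetic claims generator

The generator emulates the structure of a DPC-style hospital claims
database restricted to dyslipidemia patients, with defaults set to the
study conditions it is meant to emulate:

* **Demography.** Age ~ N(67.5, 14.3²) truncated to [16, 99] (the under-20
  tail exercises the age exclusion), 46.6% female, BMI ~ N(24.0, 4.3²),
  smoking prevalence 40%.
* **Comorbidity/co-medication.** Twelve binary covariates at claims-typical
  prevalences (diabetes 25%, cancer 20%, hypertension 14%, statin 25%, …)
  leave periodic diagnosis or prescription records so a 180-day baseline
  window recovers them; each has a log-odds effect on treatment initiation
  and a log-hazard effect on the outcome, oriented so initiators are
  younger, more metabolic and less oncologic — confounding in both
  directions.
* **Initiation.** Ever-use of the study drug is logistic in the covariates
  (10% at reference values); ever-users start after an exponential delay
  (mean 180 days) from first diagnosis, confined to a 540-day uptake
  window. Front-loaded uptake reflects how prescribing decisions cluster
  around the diagnostic work-up of a newly launched drug, keeps initiation
  uncommon (as in a national claims universe), and keeps later drop-in among
  matched controls rare. Initiators emit refill sequences with supplies
  drawn from {30, 60, 90} days, mostly short administrative gaps (≤10 days)
  with occasional long interruptions (40–240 days) and an 8% per-refill
  permanent discontinuation risk, so every gap/grace branch occurs.
* **Outcome.** Events arrive from a piecewise-constant-intensity counting
  process: baseline 3.6 × 10⁻⁵ per person-day (≈1.3 per 100 person-years,
  the order reported for fibrate-naive dyslipidemia patients), multiplied by
  the covariate effects, by exp(true_log_hr) from initiation onward, and by
  a detection surge (×2.5) during the first 180 days after the first
  dyslipidemia diagnosis — diagnostic work-up surfaces latent disease. The
  surge is what gives the naive diagnosis-anchored comparator its immortal
  time bias; time-matched groups share the same disease age and are
  unaffected. Each detected event emits the diagnosis-plus-treatment record
  pair (30% inpatient, within a generated hospitalization); 10% of events
  are diagnosis-only and 5% of outpatient treatment records go to a
  different facility, so non-qualifying records exist.
* **Missingness.** BMI and smoking are measured at lab visits spaced ≤170
  days apart (so an eligible baseline window always contains one), then all
  of a patient's BMI (resp. smoking) measurements are deleted with a
  logistic probability in age, sex and diabetes — fully observed covariates,
  hence missing at random — with the intercept calibrated by root-finding so
  the mean deletion probability hits the target (default 0.8, the missing
  fraction reported for the emulated database).

Dates are integer day offsets from 2017-12-01; all day intervals are closed.
Identical config and seed give byte-identical tables.

What the generator does **not** emulate: death or any competing risk,
calendar seasonality, coding dialect drift, fee-schedule or DPC bundling
artifacts, facility-switching, dose titration, and outcome-dependent
observation (patients are not censored by the event). Passing simulations
therefore validate the pipeline's logic and the estimator's statistical
calibration under the stated generative assumptions — not robustness to
real-world claims pathologies such as informative observation windows or
diagnostic misclassification.

## Estimator validation and problem sizes

Three simulation studies ship in `tmcohort.experiments` and are run by the
tests and the acceptance script:

* **Balance** — one confounded, complete-covariate universe of 28,000
  patients (the assembled cohort lands near 19,000 members), main-effects
  propensity fit, SMRW: the maximum absolute weighted standardized
  difference across all modeled covariates is reported, with at least three
  covariates imbalanced (>0.1) before weighting.
* **Null calibration** — 60 replicate universes of 20,000 patients with a
  null exposure effect under confounding: the SMRW-weighted robust CI covers
  HR = 1 at close to the nominal rate while the crude CI's coverage is
  materially lower.
* **Effect recovery** — 60 replicates with true log-HR = log 2, assessed on
  the per-protocol (gap/grace 90) scenario. Recovery is measured on the
  per-protocol arm deliberately: with a sustained true effect, later drug
  initiation among matched controls (drop-in) genuinely dilutes the ITT
  contrast — the weighted control group is tilted toward treatment-prone
  patients, so even rare drop-in is amplified — and censoring controls at
  drug start, which is exactly the per-protocol rule, removes that dilution
  by construction.

Replicate counts and universe sizes are the package's chosen problem sizes;
they keep Monte-Carlo error well inside the assertion margins (e.g. the
recovery mean carries a standard error near 0.015 at 60 replicates).

## Numerical choices and degenerate inputs

* Newton steps for the Cox fit are clamped to ±2 and the estimate to |β| ≤
  15 (monotone-likelihood guard); convergence tolerance 1e-12 on the step.
* Propensity scores are clipped to (1e-10, 1 − 1e-10) after the ridge
  fallback; SMRW rejects scores exactly 0 or 1.
* Standardized differences drop missing rows (pre-imputation diagnostics);
  a zero pooled variance with unequal means raises rather than returning an
  arbitrary value.
* Measurement ties on the same date resolve by record order (later row
  wins); age is completed years at 365.25 days each.
* Empty claims tables round-trip as empty datasets; empty cohorts and
  event-free scenarios raise explicit "inestimable" errors rather than
  NaNs.
* Stage seeds in the pipeline are the first spawned children of the master
  `SeedSequence`, in stage order (simulate, cohort, impute), so any stage
  can be replayed in isolation.

## Known limitations

* The weighted Cox fit supports a single (exposure) covariate — by design,
  since adjustment is via weights; additional Cox covariates would need a
  multivariate maximizer.
* The ordinal imputation model falls back to the observed margin if the
  proportional-odds fit fails on a pathological stratum; the fallback is
  logged but not flagged per cell.
* The generator's true effect switches on at initiation and persists
  (an "ever-use" effect, matching the ITT assumption that drug effects
  persist indefinitely); on-treatment-only effect dynamics are not modeled,
  so ITT/PP contrasts between scenarios should not be over-interpreted.
* Control drop-in makes the ITT contrast an attenuated estimand when the
  true effect is non-null; this is a property of the design being studied,
  not of the implementation.
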