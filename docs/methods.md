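# Methods

## Estimating equations

All eight equations return GFR indexed to 1.73 m² body surface area.
The CKD-EPI family has the piecewise power form

    eGFR = A · min(m/κ, 1)^α · max(m/κ, 1)^β · g^age · s_sex [· s_race]

per biomarker m (creatinine in mg/dL with sex-specific knot κ, cystatin C
in mg/L with knot 0.8), multiplied across both biomarkers for the
combined forms. The EKFC family rescales the biomarker by a healthy-population
median Q:

    eGFR = 107.3 / (m/Q)^x · 0.990^(age−40)   (age term only above 40),

with exponent x = 0.322 below m/Q = 1 and 1.132 above; the EKFC combined
estimate is the arithmetic mean of its creatinine and cystatin estimates.
Every coefficient sits in one declarative registry
(`gfrmon.equations.COEFFICIENTS`, exportable as JSON) so the numbers can
be diffed against the original publications in one place.

Conventions and deliberate choices:

* **Units.** The API takes creatinine in µmol/L (the usual European
  reporting unit) and converts by 1/88.4 internally; mg/dL input is
  accepted via `creatinine_unit="mg/dL"`. Cystatin C is mg/L throughout.
* **Race term.** The 2009/2012 CKD-EPI race coefficient is implemented
  behind `apply_race_term` and OFF by default, matching contemporary UK
  practice; the 2021 CKD-EPI and EKFC equations have no race term and
  ignore the flag by construction.
* **EKFC Q values.** Creatinine Q uses the adult sex-specific constants
  (80 µmol/L men, 62 µmol/L women) for all ages ≥18; the young-adult
  age-interpolated Q below 25 years is not implemented because the
  package targets adult CKD cohorts (median age near 67). Cystatin Q is
  the published age-dependent, sex-free form: 0.83 mg/L below age 50,
  increasing by 0.005 mg/L per year above 50.
* **No pediatric branches**: ages below 18 are rejected.

The implementation is verified row-by-row against an independently
written flat-arithmetic oracle (`scripts/conformance_oracle.py`; fixture
committed in `tests/data/equation_conformance.csv`), and property tests
check strict monotonicity in each biomarker, non-increasing age response,
and continuity at every piecewise knot to ~1e-9 relative.

## Staging and progression

KDIGO G-categories partition GFR at 90, 60, 45, 30 and 15 mL/min/1.73 m².
Intervals are half-open with the lower bound in the *less severe*
category (exactly 45 → G3a, exactly 15 → G4): the printed clinical ranges
("45–59", "30–44") are integer-labelled, so a convention must be fixed,
and this one keeps a value on a published boundary in the category whose
label contains it. Progression between two visits requires both
(i) a relative GFR reduction ≥25% (inclusive) and (ii) a strictly worse
G-category at follow-up, of any number of steps. Albuminuria-based
staging is out of scope; the classifier is GFR-only.

## Slopes and large errors

* `elapsed_years` divides the exact calendar interval by 365.25 days.
* The primary slope is the two-point statistic
  (follow-up − baseline)/Δyears for each source (measured GFR or one
  equation's estimates).
* Percent slopes divide the slope by the *observed baseline value* of the
  same source (not a fitted intercept), so a −5 mL/min/1.73 m²/yr slope
  from baseline 50 is −10 %/yr.
* Per-individual OLS slopes regress the source value on years since that
  participant's first visit.
* The mixed-model variant fits one linear mixed-effects model to the
  cohort's measured-GFR visits: fixed intercept and slope in time,
  per-participant random intercept and random slope with an unstructured
  2×2 covariance, maximum-likelihood (not REML) estimation. The
  per-participant slope is the population slope plus the participant's
  predicted (BLUP) random slope. Optimization tries the gradient-based
  statsmodels chain, then Powell; if nothing converges the function
  returns per-individual OLS slopes flagged `used_ols_fallback`. When
  the data are exactly linear within participants (zero residual
  variance) the likelihood is unbounded, so that case is detected and
  the exact limit — per-individual OLS — is returned directly. Note a
  single-visit participant's BLUP is *close to* but not exactly the
  population slope: the observation informs the random intercept, which
  is correlated with the random slope.
* A slope error (estimated − measured) is a **large error** when
  |error| ≥ 3 mL/min/1.73 m²/yr (inclusive) or when the percent-scale
  error is strictly beyond ±5 %/yr. The differing boundary inclusivity
  mirrors the criteria's usual statements (≥±3 vs >±5%); it is
  irrelevant for continuous data but fixed for exactness on constructed
  cases. Both thresholds are configurable in `RunConfig`.

## Agreement, paired comparisons, diagnostic accuracy

All proportions carry exact Clopper–Pearson 95% intervals in
beta-quantile form (lower bound 0 at k=0, upper bound 1 at k=n); the
implementation is tested against a bisection inversion of the binomial
tails for every (k, n) with n ≤ 50. McNemar's paired test reports both
the exact two-sided binomial p-value on the discordant pairs and the
asymptotic chi-square without continuity correction; the exact p is
primary when there are ≤25 discordant pairs (where the asymptotic
approximation is weakest). The paired agreement difference is reported
with a Wald paired-proportion CI, labelled as such — other CI
constructions for this quantity exist, and the point difference is the
comparable statistic.

Progression detection treats measured-GFR progression as the reference
and each equation's progression call as the index test; sensitivity,
specificity, PPV and NPV each carry exact CIs, and a metric with a zero
denominator is reported as missing rather than imputed. P30 is the
fraction of estimates within ±30% (inclusive) of the paired measured
GFR. Bias is the median of (estimated − measured) at a timepoint;
longitudinal change is summarised as median (IQR) of follow-up − baseline
per source and progression group.

No multiple-testing adjustment is applied anywhere: the compared
equations share biomarkers and participants, so Bonferroni-style
corrections would be conservative; p-values are reported as computed.
Report tables round half-up to 1 decimal; machine outputs keep full
precision.

## Synthetic cohort generator

The generator emulates a three-year prospective monitoring design:

* **Demographics.** 57.7% male; ages from a two-piece normal fitted to
  median 67.1 (IQR 58.1–73.6), truncated to [18, 95]. The side-SD fit is
  bounded away from degeneracy (the exact quantile-matching root
  collapses one side), leaving residuals of a fraction of a year on the
  target quantiles.
* **Baseline truth.** True baseline GFR is log-normal calibrated to
  median 48.1, IQR 40.2–57.2 mL/min/1.73 m².
* **Trajectories.** Linear in time (the slope framework's own
  assumption), floored at 6 mL/min/1.73 m². A mixture defines the truth:
  15.9% progressors with slope ~ Normal(−5.5, 1.5²) mL/min/1.73 m²/yr,
  the rest ~ Normal(−1.0, 1.5²). The means/SDs are implementer-chosen
  defaults — not estimates from any dataset — selected so progressors
  lose a median of roughly 16 mL/min/1.73 m² over three years against
  roughly 3 in non-progressors, the regime in which a ≥25% +
  category-drop rule captures a realistic minority of participants.
* **Observation model.** Measured GFR is truth × LogNormal(0, 0.05);
  biomarkers are generated by *inverting* a generating equation
  (creatinine via CKD-EPI 2009, cystatin via CKD-EPI 2012 by default) at
  the GFR the biomarker "sees" — truth multiplied by a person-level
  LogNormal(0, 0.10) bias and an optional non-GFR drift exp(δ·t) — then
  multiplied by visit-level LogNormal(0, 0.05) noise. The 5% CVs are
  assumptions plausible for iohexol clearance and standardised assays.
  Positive drift δ makes the biomarker-implied GFR decline more slowly
  than the truth, reproducing the clinically reported *underestimation*
  of GFR decline by estimating equations (e.g. falling creatinine
  generation as muscle mass declines). With all noise terms zero the
  generating equations reproduce measured GFR exactly — the limit in
  which the pipeline must show 100% agreement and perfect detection.
* **Schedule and attrition.** Biomarkers at months 0, 6, …, 36; measured
  GFR at 0 and 36 for everyone plus 12- and 24-month subsets scaled from
  215/875 and 188/875; visit dates jittered ±14 days around the nominal
  month (baseline exact). `n_participants` is the *evaluable* target:
  the generator recruits n/(1 − attrition) participants (default
  attrition 1 − 875/1229) and censors the dropouts before 36 months, so
  the recruited → evaluable bookkeeping mirrors a real flow diagram.
* Equation inversion is vectorized bisection on the log-concentration
  scale (60 halvings, far below 1e-8 relative error); two-marker
  equations fix cystatin at its own single-marker inversion and solve
  creatinine. All randomness flows from one `numpy` Generator seeded by
  `SimulationConfig.seed`; identical seeds give byte-identical cohorts.

What the generator does *not* emulate: nonlinear or hinged trajectories,
informative dropout, albuminuria dynamics, comorbidity structure, and
GFR-level-dependent equation bias (the cross-sectional bias profile of
real equations varies with GFR; here person-level bias is
level-independent). Passing parameter-recovery tests therefore shows the
*machinery* is correct under the stated generative assumptions, not that
any equation performs equivalently on real cohorts.

## Pipeline conventions

The evaluable cohort is the **intersection** complete-case set:
participants with measured GFR and every configured equation's estimate
at both baseline and a follow-up at least `min_followup_years` (default
2) later, so every table shares one denominator. Counts at each
filtering step are logged and written to `run_log.json` together with
the seed and a config digest. Estimation uses age at baseline (the
cohort table's demographic anchor) for all visits. Reports are written
deterministically; re-running with the same config and input reproduces
byte-identical files.

Problem sizes in the shipped tests and acceptance script — an 875-
evaluable default cohort, a 300-participant drift cohort, and 10⁴ random
panels for the property suite — are the package's default study
conditions and keep a full run to a couple of minutes on one CPU.

## Known limitations

* The mixed model is time-only (no covariates) and assumes linear
  individual trajectories.
* The paired-difference CI method is Wald-on-discordant-counts; exact
  methods for paired differences are not implemented.
* The EKFC young-adult creatinine Q interpolation (ages 18–25) is
  omitted; estimates in that narrow age band use the adult constants.
* Progression calls compare single baseline and follow-up values; no
  sustained-decline or confirmatory-measurement logic is applied.
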