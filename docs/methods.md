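# Methods

## Scope and design

`xenoeq` studies when a waitlisted kidney patient reaches clinical
equipoise between accepting a xenotransplant with assumed graft survival
*n* and remaining on the allotransplant waitlist. Real analyses of this
question run on restricted national registries; this package instead ships
a synthetic registry generator with known ground truth and builds every
analysis stage against it. Passing tests therefore demonstrate that the
*method* is implemented correctly (estimators recover planted parameters,
integrators match closed forms, counterfactual orderings behave as the
theory predicts) — they do not validate any quantitative claim about real
waitlist populations.

## The synthetic registry

One row per waitlist registration. Covariates: age at listing drawn from a
mixture over the 18–49 / 50–64 / 65+ bands (weights 0.35 / 0.45 / 0.20,
uniform within band, upper bound 80); diabetes Bernoulli(0.45); blood type
O/A/B/AB with probabilities 0.48/0.34/0.14/0.04; previous transplant
Bernoulli(0.12); CPRA zero-inflated (65 % exactly 0, 30 % uniform on
[1, 99], 5 % uniform on [99.5, 100] so the highly sensitized cohort is
populated); BMI ~ N(28, 5²) clipped to [15, 50]; albumin ~ N(3.9, 0.5²)
clipped to [1.5, 5.5]; a social-deprivation index uniform on [0, 100]; and
three comorbidity flags (COPD 0.10, peripheral vascular disease 0.15,
smoking 0.12) that carry no hazard by default. These frequencies are
round-number choices in the range of published U.S. waitlist descriptive
statistics; they are study conditions, not tuning knobs.

Events come from independent latent Weibull proportional-hazards times —
death-or-delisting, transplant — plus exponential administrative censoring,
truncated at the 25-year horizon; the observed outcome is the earliest.
Death and delisting-for-illness are merged into one absorbing event: the
analysis targets patients at risk of dying *or* becoming too sick to
transplant. Defaults (log-hazard-ratios on centred/scaled design columns):

| process | baseline /yr | shape | coefficients |
|---|---|---|---|
| death/delisting | 0.11 | 1.1 | diabetes 0.50, age 0.35/decade, albumin −0.30/0.5 g/dL, SDI 0.15/25 pts |
| transplant | 0.085 | 1.4 | blood B −0.50, O −0.40, AB 0.30, CPRA −1.2 (0→100 %), prior transplant −0.30, age −0.15/decade, diabetes −0.20 |
| post-transplant death | 0.075 | 1.0 | age 0.35/decade, diabetes 0.40, donor quality −1.0 (0→1) |

The transplant shape 1.4 encodes waiting-time priority accrual (rising
hazard with time listed); blood B/O and high CPRA slow matching; the
post-transplant hazard is well below the waitlist death hazard, so
transplantation is genuinely beneficial in the ground truth — a premise the
incentive orderings rely on. Recipients are matched to a uniform random
donor (quality ~ Beta(3, 2)); post-transplant follow-up is truncated at the
horizon measured from listing. Graft failure among recipients is
Bernoulli(0.35) and relisting given failure is logistic (intercept 0.5,
age −0.40/decade, diabetes −0.30). Each patient's `waiting_time_elapsed`
is a uniform fraction of their outcome time — a snapshot of a patient
observed mid-course — and 10 % of registrations are inactive; every
analysis stage excludes inactive patients.

The offer log generates marginal (donor quality < 0.35) and standard
offers as per-patient Poisson streams (0.6 and 0.4 per patient-year of
exposure). Whether an offer is *seen* is Bernoulli in the center's opt-in
screen propensity (~ Beta(5, 2)); acceptance, conditional on seen, in the
center's acceptance propensity (~ Beta(2, 2)). The offer log exists to
drive the aggressiveness score and is deliberately decoupled from the
latent transplant times. Randomness is split into per-table streams
spawned from one seed, so enlarging the donor pool does not perturb the
patient table.

What the generator does **not** emulate: real registry file layouts and
their cleaning/imputation rules, ZIP-code geography (the deprivation index
is sampled, not constructed), multi-listing, era effects, and any
correlation structure between covariates beyond what the hazards induce.

## Survival estimation

Three right-censored targets: waitlist death (transplant treated as
censoring), time to transplant (death treated as censoring; an
Aalen–Johansen competing-risks variant is provided as a sensitivity check),
and post-transplant death. Backends: Cox proportional hazards (lifelines,
Efron tie convention), random survival forest (scikit-survival, seed
recorded in the model object), Kaplan–Meier. Cox and KM models are reduced
at fit time to arrays — coefficients, covariate means, baseline survival on
the monthly grid — which makes prediction a vectorized power transform and
serialization plain JSON; the baseline is the step-function Breslow
estimate carried forward between event times and beyond the last one (no
tail extrapolation). Zero-variance covariates are dropped with a logged
warning; a target with no events raises.

Life expectancy is the restricted mean survival time: trapezoidal
integration of the curve on the monthly grid over [0, H], H = 25 years.
Conditional curves are S(e + t)/S(e), re-gridded from zero. Variable
importance is the absolute standardized coefficient for Cox and
permutation importance of Harrell's concordance (10 seeded repeats) for
RSF. Kaplan–Meier bands are Greenwood log-log (exponential Greenwood) 95 %
intervals; any stratum with fewer than 15 events is reported suppressed
rather than estimated.

## Equipoise

`le_status_quo` is the RMST of the patient's waitlist-death curve
conditional on the waiting time already served (elapsed times snapped to
the monthly grid; the conditioned curve is carried forward to the full
horizon window). `le_xeno = n + p_relist · le_relist`. The relisting
probability is estimated from relisting after allograft failure, either as
a cohort-level empirical fraction or an individual-level logistic model —
a config switch, cohort-level by default. CPRA is held fixed after
xenograft failure (a hook exists for sensitization shifts, off by
default). Viability is a strict inequality; ties are non-viable. Under the
base scenario `le_relist` does not depend on *n*, so viable sets are
nested along the sensitivity grid by construction.

Note one deliberate asymmetry: the status-quo side is the *waitlist
survival* curve (it does not credit a possible future allotransplant),
mirroring the construction of the comparison as "survival waiting for an
allograft" versus "survival with a xenograft". The window mismatch — the
xenograft side effectively spans n + H years — is inherent to the
`n + p·LE` formula and documented rather than corrected.

## The scenario recursion

Life expectancy after relisting is computed on the monthly grid as

    LE = ∫ S_death(t)·S_no-tx(t) dt + Σ_j ΔF_tx(j)·S̄_death(j)·LE_post(t_j),

midpoint rule within intervals, so waiting person-time and post-transplant
person-time are each counted exactly once. `LE_post(t)` is the RMST of the
post-transplant Cox model for the patient aged to the transplant date,
matched to a donor of mean pool quality, truncated at the remaining
horizon H − t; it is tabulated on a dense grid of linear-predictor values
and interpolated, which makes the recursion a few array operations per
scenario. Against the constant-hazard closed form
1/(μ_w+λ) + λ/(μ_w+λ)·(1/μ_p) (horizon-truncated analogue) the recursion
agrees to better than 0.1 % on a 3×3×3 hazard grid.

Scenario definitions:

* **base** — waiting time resets to zero at relisting. Covariates are
  frozen at prediction time (age advances by the waiting time already
  served, but not by the *n* years on the xenograft, keeping the base
  scenario independent of *n*).
* **inactive_accrual** — the time-to-transplant curve (only) is
  conditioned on a waiting-time credit of w₀ + n: the credit is an
  allocation-priority construct, so the death curve is untouched. With the
  transplant shape > 1, the credit accelerates matching.
* **living_donor_priority** — the transplant survival function is raised
  to the priority multiplier (default 5), i.e. a proportional-hazards
  boost; a multiplier of 1 reproduces the base exactly. The multiplier is
  a minimal surrogate for point-based allocation mechanics, which live in
  match-run data this package does not model.
* **highest_priority** — immediate transplant with an ideal organ: the
  blood-compatible donor pool (O→all, A→A/AB, B→B/AB, AB→AB) is scored by
  post-transplant LE and the q-th percentile (nearest rank, q = 75)
  returned. Nearest rank keeps the statistic deterministic and
  interpolation-free.

Under the defaults the per-cohort incentivized fractions are ordered
base ≤ inactive_accrual ≤ living_donor_priority ≤ highest_priority across
the whole sensitivity grid, which is the qualitative structure the
counterfactuals are designed to exhibit; the magnitudes are properties of
the synthetic conditions.

## Evaluation

Identification uses "≤ τ" (inclusive). Patients censored before τ without
death are excluded from both denominators — including them would bias the
hit rate downward by an unknowable amount; the policy string is recorded
in every report. Transplanted-before-τ patients remain as non-cases: they
left the waitlist alive. Undefined rates (empty denominators) are flagged,
never reported as zero, and reports with fewer than 15 correct
identifications carry a suppression flag. An independent brute-force
recount (`oracle_confusion`) is part of the public API and the test suite
asserts exact count equality against it.

## Pipeline

The six stages communicate only through on-disk artifacts (CSV tables,
JSON models, a JSON manifest of SHA-256 digests), so the whole chain is
re-runnable stage by stage and two runs with the same config and seed are
digest-identical. Config is YAML over documented defaults with unknown-key
rejection. The pipeline's fitting backend is Cox: scenario analysis needs
a curve for every patient × scenario × n, which the array-form Cox models
deliver in milliseconds; RSF remains available through the library API for
model comparison and importance ranking. Default problem sizes — 10,000
patients, 20 centers, 3,000 donors — run the full chain in a few seconds
on one CPU.

## Numerical conventions

Monthly grid (1/12 year), left endpoint 0; trapezoidal RMST; curves
clipped to [0, 1] and forced non-increasing after interpolation; elapsed
times snapped to the nearest grid point (sub-month precision is irrelevant
at year-scale reporting); aggressiveness tertiles take the ⌊n/3⌋ best and
worst scores with ties broken by center id; survival-model events below 50
trigger a warning, below 1 an error.

## Limitations

* Latent independence of the death and transplant processes (given
  covariates) is assumed by both the generator and the recursion.
* The waiting-time covariate acts through conditioning and duration
  dependence (Weibull shape), not as a time-varying regression covariate.
* Aging during the xenograft's functioning life is ignored; sensitization
  after xenograft failure is assumed away (CPRA fixed).
* The offer log is independent of the latent transplant times, so
  aggressiveness is a descriptive center covariate here, not a causal
  driver of transplant hazard.
* DeepSurv-style neural survival backends are out of scope; the model
  contract (curve on the monthly grid) accommodates adding one.
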