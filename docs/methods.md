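# Methods

## Scope and model

`ckdsim` implements a complete in silico treatment-selection pipeline for
chronic kidney disease built on a urinary-peptide risk classifier:

1. **Scoring.** A profile is a map peptide id → non-negative intensity,
   with missing values denoting signals below the CE-MS detection limit.
   Missing values are imputed to exactly zero before any computation; the
   scorer refuses un-imputed profiles so this step is always explicit. The
   classifier is linear, `score = b + Σ w_j f(x_j)`, with an elementwise
   transform `f`. The production classifier this stands in for is a
   proprietary SVM whose kernel and preprocessing are not public; the
   downstream procedure only requires a deterministic profile → score map,
   so the classifier is a pluggable, serialisable component. `log1p` is
   the default transform because zero (the imputation value) is in its
   domain; `identity` is available. Panel peptides absent from a profile
   contribute `f(0)`, consistent with the below-detection-limit reading.
2. **Interventions.** An intervention is a per-peptide fold-change table
   (mean abundance after treatment / before). Application multiplies
   intensities; a zero intensity stays zero (a peptide below detection
   limit remains so — imputation is performed once on the baseline
   profile, not repeated after treatment). Combinations multiply the
   member tables' fold changes per peptide, treating effects as
   independent; this commutes and associates, and the engine's combined
   application is property-tested against sequential application. All
   2^k − 1 non-empty subsets of the k available interventions are scored
   per patient and the minimum-score regimen selected. Score ties are
   broken toward fewer interventions, then lexicographic order: parsimony
   minimises drug burden when extra components add nothing. Regimen
   enumeration order (size, then lexicographic) is fixed so outputs are
   byte-stable.
3. **Recalibration.** Short-term (6-week to 9-month) fold changes are
   rescaled per intervention so the model-predicted percentage change in
   time-to-50%-MAKE-risk matches the percentage observed in that
   intervention's randomized trial. The correction factor
   r = observed% / predicted% is applied by **power scaling**
   (`fc ← fc^r`, i.e. log fold changes scaled linearly by r). This form
   was chosen over the linear alternative `1 + r(fc − 1)` because it
   preserves positivity for every r, commutes with multiplicative
   combination, and makes r = 1 an exact identity and r = 0 an exact null.
   The predicted effect is the cohort **median** of per-patient percentage
   T50 changes (robust; the mean is available). Because the predicted
   effect is nonlinear in the exponent, a single pass does not land
   exactly on the observed value; both a single-pass mode (the default)
   and a damped fixed-point mode are provided. In the iterative mode,
   passes after the first clip |r| into [1/3, 3] to prevent oscillation,
   and when the target is unreachable (the predicted effect saturates —
   possible because `log1p` flattens as intensities are driven to zero)
   the best iterate is returned with a non-convergence warning rather than
   an exception. Calibrating a score-neutral (identity) table raises an
   explicit error, since observed/0 is undefined.
4. **Risk transform.** The empirical time to 50% MAKE risk at a target
   score selects the 100 nearest scores (50 strictly above, 50 at or
   below; the 100 nearest overall when one side is exhausted near the
   distribution's extremes — the boundary rule is this package's choice),
   then computes (Σ follow-up days)/(events)/2: person-time over events is
   the average time to the event, and halving it gives the time to 50%
   cumulative risk under linear accrual. Distance ties are broken by
   patient id for reproducibility. Ordinary least squares of log10(T50) on
   score gives the log-linear risk model; the published coefficients
   (4.1446, −0.9498) are built in as named constants and drive risk
   outputs by default, with a `refit` mode for parameter-recovery work.
   The logarithm is base 10: base e would put the score-zero horizon at
   ~63 days, irreconcilable with the published incidence rates.
   Incidence per 100 person-years is `50 / T50(years)` with 365.25
   days/year — 50 events among 100 patients accrued over T50; this
   conversion and day count reproduce the published median rates (4.5 at
   score 0.565; 1.43 at 0.039) exactly at their printed precision. The
   relative risk reduction for a score drop Δ is `100(1 − 10^{bΔ})`,
   which is 0 at Δ = 0 and ≈ 88.8% at Δ = 1 for the published slope.
   Both transforms are strictly monotone in the score for b < 0, so
   cohort medians of rates equal rates at median scores.
5. **Cohort statistics.** Tertile stratification cuts at the empirical
   1/3 and 2/3 quantiles with ties going to the lower stratum (an
   all-equal cohort is entirely "low"). The high-versus-low tertile
   hazard ratio comes from a single-binary-covariate Cox model whose
   Breslow partial likelihood is maximised by safeguarded Newton
   iteration (closed-form score and information; step halving; |β| capped
   at 15 so complete separation returns a bounded estimate instead of
   diverging), with Wald 95% intervals. The paired before/after score
   comparison is a Wilcoxon signed-rank test (zeros dropped, exact null
   distribution up to 25 nonzero pairs, normal approximation with
   continuity correction beyond); the baseline-versus-benefit association
   is a Spearman rank correlation on the signed deltas (after − before).

## Synthetic cohort generator

The generator produces cohorts with the statistical structure the
analysis assumes, so everything is testable without data access. Defaults
mirror the published study cohort and are fixed once:

| parameter | default | rationale |
| --- | --- | --- |
| n_patients | 935 | study cohort size |
| n_peptides | 1,500 | order of sequenced urinary peptides retained in CE-MS studies, kept moderate for memory |
| n_classifier_peptides | 273 | CKD273 panel size |
| missing_rate | 0.25 | typical below-detection-limit fraction |
| score_location / scale | 0.565 / 0.30 | printed median; spread between the printed 95% interval (σ≈0.26) and IQR (σ≈0.46) readings |
| followup median / max | 1.5 y / 5 y | printed follow-up summary 1.50 (0.35, 5.0) years |
| risk intercept / slope | 4.1446 / −0.9498 | published coefficients as generative truth |

Intensities are log-normal per peptide; each cell is missing
independently with probability `missing_rate` (the spec'd simplification
of left-censoring; intensity-dependent missingness is not modelled).
Baseline scores are calibrated per patient: up-weighted markers are
scaled by e^u and down-weighted markers by e^−u, making the induced score
strictly monotone in u, and u is solved by vectorised bisection so each
patient's score matches a draw from N(score_location, score_scale). The
returned "true scores" are the exact classifier scores of the generated
profiles.

Event times are exponential with mean 2·T50(score): under linear accrual
T50 is half the mean time to event, and the exponential is the simplest
law whose person-time/events estimator is consistent with that mean —
parameter recovery is then a well-posed test (a 10,000-patient uncensored
cohort recovers both coefficients within ±0.15). Censoring is log-normal
follow-up (median 1.5 y, log-sd 0.8) truncated at `followup_max_years`;
`inf` disables censoring. At the defaults this yields on the order of
70–100 events per 935 patients, matching the scale of the study's 71.

Fold-change tables cover a random ~35% of the classifier panel plus 50
off-panel peptides. Log fold changes are N(−sign(w)·0.05, 0.5²) on-panel
(biased toward reversing each marker, i.e. beneficial, because the source
trials were efficacious; the bias is a parameter so neutral or adverse
interventions can be generated) and N(0, 0.5²) off-panel. The noise sd
0.5 reflects the magnitude spread of published treatment fold changes
(commonly 0.5–2×); keeping the bias small relative to the noise makes
individual interventions heterogeneous across patients after
recalibration, so the optimal regimen varies realistically across the
cohort instead of collapsing onto the full combination.

The default trial effects used by the synthetic pipeline
(`DEFAULT_TRIAL_EFFECTS`: ARB 20, Exercise 15, GLP1RA 25, MRA 25,
OliveOil 10, SGLT2i 35 percent improvement in time to MAKE) are
illustrative magnitudes graded by the strength of kidney-outcome evidence
per class; real analyses must supply trial-derived values.

What passing tests on synthetic data do **not** show: the generator has no
batch effects, no intensity-dependent missingness, no correlation between
baseline score and treatment responsiveness (so the negative
baseline-versus-benefit rank correlation reported for the real cohort is
not reproduced — the synthetic association is ≈ 0), and a linear
classifier rather than an SVM. Study-specific numbers (the exact hazard
ratio, regimen frequency table, or the 61% median relative risk
reduction) depend on the real cohort and are checked only as
distributional properties (score reduction significance, HR > 1 with CI
excluding 1, count conservation).

## Numerical choices

- All randomness flows from one integer seed through fixed per-operation
  substreams (`numpy` `SeedSequence` spawn keys); identical spec + seed
  reproduces every array bit-identically, and report CSVs are written
  with a fixed float format so files are byte-stable.
- Score-target bisection runs 50 iterations on u ∈ [−30, 30]; patients
  with no detectable marker on one side of the panel get the nearest
  achievable score (with every marker missing the score is exactly the
  classifier bias).
- The Newton solver for the Cox model iterates to a 1e-12 step tolerance
  with monotone step halving; its estimate is verified in tests against a
  two-stage grid search of the same partial likelihood (1e-4) and against
  lifelines on tie-free data (where Efron and Breslow coincide).
- Optimal-regimen ties are exact float ties (identical arithmetic paths
  produce identical scores for no-op tables); the first minimum in
  canonical order implements the documented tie-break.
- Degenerate inputs are first-class: empty fold-change tables are no-ops,
  an eventless neighbour window or a sub-100 cohort raises a typed error,
  constant inputs to rank statistics raise (the pipeline records NaN and
  continues), and an all-zero-difference Wilcoxon returns a flagged
  degenerate result.

## Problem sizes in the test suite

Routine tests run on 50–935-patient cohorts with 80–1,500 peptides; the
estimator-consistency and parameter-recovery checks use one shared
10,000-patient uncensored cohort with a 100-peptide panel, and oracle
comparisons use 100 random 12–15-peptide instances. The full suite runs
in well under a minute on a single CPU.

## Known limitations

- Pharmacological interactions are not modelled; combination effects are
  purely multiplicative on peptide abundances.
- Whether the original procedure re-imputed after intervention, iterated
  its recalibration, or summarised predicted effects by median or mean is
  not documented; this package's choices (carry baseline zeros forward,
  single-pass default with an iterative option, median) are stated as its
  own and kept behind explicit parameters.
- The person-time estimator assumes linear risk accrual; no Kaplan–Meier
  or parametric survival alternative is provided.
- The synthetic generator's uniform-random missingness and
  response-homogeneous patients understate the structure of real
  peptidomics cohorts (see above).
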