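# Methods

This note documents the models and procedures implemented in
`cmtiming`, the defaults and why they were chosen, the numerical
decisions that matter, and what the synthetic cohorts do and do not
establish about real data.

## Chronology scoring

A chronology is a 10-subscale × 18-year grid of weighted severity
scores in [0, 10].  The item→subscale weighting that produces these
scores belongs to the instrument's own scoring algorithm and is treated
as an upstream, pluggable transform: the engine accepts subscale-year
severities already on the 0–10 scale.

* **Type aggregation.**  Each CM type's year score is the *mean* of its
  constituent subscales for that year (ABUSE averages five subscales,
  NEGLECT two, PEER two, SEXA one).  The mean keeps every type-year on
  the common [0, 10] scale and lets each subscale contribute;
  `rule="max"` (worst constituent) is available.
* **Infantile-amnesia exclusion.**  Ages 1–2 are dropped from the
  type-by-age predictors only.  The global indices default to the full
  1–18 record — the exclusion is motivated by the unreliability of
  *year-resolved* recall, which the year-aggregated indices do not
  depend on — and can be restricted to 3–18 via `global_age_window`.
* **Global indices.**  A subscale's overall severity is its peak year
  score; SEVERITY sums these over the ten subscales (range exactly
  0–100).  MULTI counts subscales whose overall severity strictly
  exceeds the subscale's threshold; DURATION counts years in which any
  subscale-year exceeds its threshold.  Published instrument thresholds
  are not bundled; `ThresholdTable` defaults to 0.5 on every subscale
  (any non-trivial endorsement counts) and loads user-supplied values
  from YAML.

## Synthetic cohorts

The generator emulates the statistical structure the analysis must
survive, not any particular sample:

* **Exposure dynamics.**  Per subscale, exposure follows a two-state
  Markov chain whose marginals track a per-age prevalence curve.  With
  persistence `r`, the stay probability is `p_t + r (1 − p_t)`; `r = 0`
  gives independent years, `r = 1` absorbing exposure, and the marginal
  prevalence is exact for flat curves at every `r`.  (Note `r` is an
  interpolation weight toward certain continuation, not the raw
  continuation probability itself — the parameterization that makes
  "no persistence" coincide with independence.)
* **Co-occurrence.**  Each year's innovations across the ten subscales
  are coupled by a Gaussian copula; the default correlation is 0.5
  within a CM type and 0.2 across types, reflecting the strong
  interrelation of maltreatment forms in high-risk samples.
* **Severity given exposure** is `0.5 + 9.5·Beta(2, 5)` (mean ≈ 3.2),
  chosen as a right-skewed severity profile on (0.5, 10]; the floor at
  the default scoring threshold makes "exposed" and "above threshold"
  coincide, so prevalence curves are directly interpretable.  The true
  within-year severity distribution of real instruments is not
  published; only qualitative fidelity is claimed.
* **Default prevalence profile.**  Neglect near ceiling (~0.9 per age
  for the type), parental abuse common (~0.6–0.75), peer violence rare
  before school age and peaking in adolescence, sexual abuse < 10 % at
  every age.  One consequence is acknowledged: with neglect near
  ceiling per age, essentially every synthetic subject has some
  above-threshold exposure, so the "share with any CM" saturates near
  100 % — higher than real-cohort figures, where validated thresholds
  sit well above raw endorsement.
* **Outcomes.**  T-scores are `50 + Σ w_j z_j + N(0, noise_sd)` with
  `z_j` the cohort-standardised planted predictor and `noise_sd = 9` by
  default, keeping total SD near the ASEBA population SD of 10 under
  the default planted effects (global burden drives internalizing,
  early parental abuse drives externalizing).  Spectrum diagnoses are
  Bernoulli draws from a logistic link on the same linear predictor
  (slope 0.25, intercepts −1.0/0.0), giving diagnosis rates near those
  of high-risk samples (~1/3 internalizing, ~1/2 externalizing); the
  any-diagnosis indicator is their union.
* **Covariates.**  Sex (40 % female) and age (26 ± 3 years) influence
  outcomes only if named in the effect map; default none.

What passing tests on these cohorts show: the pipeline recovers planted
effects, respects its published ranges, and is calibrated under its own
generative assumptions.  What they do not show: robustness to recall
bias, informative missingness, item-level measurement error, or
outcome distributions far from Gaussian — none of which the generator
emulates.

## Importance engine

* **Base learner.**  A subsampled tree ensemble (63.2 % subsamples,
  √p candidate predictors per node, minimum node size 5, 500 trees by
  default).  The default split rule draws random split points per
  candidate feature ("random" criterion), which blunts the selection
  bias toward many-valued predictors that exact variance-reduction
  splitting exhibits on collinear score matrices — the same concern
  that motivates conditional-inference forests — at a fraction of the
  cost; exact CART splitting is available via
  `split_criterion="variance"`.  Numerical equivalence with any
  particular forest implementation is not a goal: the importance
  statistic is defined by the permute-refit procedure, not by the
  learner.
* **Permute-refit ΔMSE.**  The scored column is permuted across the
  *full* cohort before the 75/25 split, so train and test both see the
  broken association; the refit uses the same learner seed as the
  intact fit, isolating the permutation's effect.  A constant column's
  permutation leaves the data identical, so its importance is exactly
  0.  Negative ΔMSE values from sampling noise are retained unclipped
  to keep the null calibration unbiased.
* **Reproducibility.**  Every random decision (split, learner,
  permutation, reshuffle) draws from its own stream keyed by the master
  seed, repetition index and column index, so results are identical
  regardless of execution order or predictor subsetting, and a fixed
  master seed reproduces outputs byte for byte.
* **Missing data** are refused, not imputed.

## Null calibration

The observed importance is a mean over `k` split repetitions, so its
null sampling variance is `v_b + v_w/k`: a between-reshuffle component
plus within-outcome procedure noise.  At cohort sizes of a few hundred
the procedure noise `v_w` (split, subsampling and permutation
randomness) dominates the between-reshuffle component by an order of
magnitude.  Two consequences drive the design:

1. A null built from *single-split* replicates has variance
   `v_b + v_w`, overstating the reference SD several-fold at k = 25
   and making the Z-test severely conservative — it flags essentially
   nothing at conventional levels.  Moment corrections that subtract
   an estimate of `v_w` are numerically ill-conditioned (two nearly
   equal noisy variances) and were rejected.
2. Null replicates therefore repeat the full k-split averaging by
   default, making them exchangeable with the observed statistic under
   H0.  With a modest number R of replicates, p-values use the exact
   finite-R reference `t_{R−1}` on
   `(VI − null mean)/(null SD · √(1 + 1/R))`, which is the correct
   small-R analogue of the Z-test and converges to it as R grows; at
   the study scale of thousands of reshuffles the two coincide.
   Shallower nulls remain available (`null_split_reps`) and are scored
   with the plain Z-test, documented as conservative.

One-sided upper-tail testing is used throughout (chance can only make
an importance look *high*); no multiple-testing correction is applied
by default, matching the convention of reporting per-predictor raw
p-values, with Benjamini–Hochberg available (`fdr=True`).  A predictor
with zero null SD is flagged degenerate and excluded from significance
calls.  Observed and null pipelines are asserted (by config hash) to
share every setting except the outcome reshuffle.

Competitive comparison reports the strongest member of the global
group (SEVERITY/MULTI/DURATION) against the strongest type-by-age
cell; exact ties are broken lexicographically and flagged.  Selection
for diagnosis validation takes the strongest *significant* type-by-age
cell per CM type; types with none are omitted.

## Diagnosis validation

ICD-10 F-codes map to HiTOP spectra by longest-prefix match over the
published pattern lists, so sub-code patterns beat stem ranges
(F60.31 → internalizing although F60.3 → externalizing).  Two quirks
of the printed lists are kept as printed and handled as unions: the
internalizing list names both F41 and F40–F42, and the externalizing
range F10–F25 sweeps in the psychotic codes F20–F25.  Unparseable
codes are excluded with a warning rather than failing a subject.

Each selected predictor enters its own binomial GLM (logit link) for
the disorder indicator with sex and age as covariates — one model per
predictor, matching the predictor-wise reporting convention.
Predictors are z-scored by default so ORs are per SD and comparable
across scales (`standardize=False` for raw-scale coefficients).
Quasi-complete separation is flagged on the returned fit, not raised.
Welch's t (Satterthwaite df) and Cohen's d (pooled SD) cover the
descriptive group contrasts.

## Scaled study sizes

Analyses and tests run at desk scale; the full-fidelity configuration
(500 trees, 100 split repetitions, thousands of null replicates) is a
config change, not a code change.  Sizes used by the shipped analyses
and the acceptance checks, chosen as the package's own working scale:

* importance engine in tests: 8–30 trees, depth 4–6, 3–25 split reps;
* type-I-error calibration: 50 cohorts of n = 400 with
  outcome-independent predictors, k = 25 split reps, R = 8 full-depth
  null replicates (200 refit units per cohort), on a 4-predictor
  matrix — the calibration property does not depend on predictor count
  or ensemble size;
* planted-effect recovery: 20 cohorts of n = 500, planted weight half
  the noise SD, 5 split reps;
* GLM recovery: n = 2000, planted logistic slope 0.5 per SD.

## Known limitations

* The generator emulates subscale-year severities directly; item-level
  questionnaire structure, recall error and missingness are out of
  scope.
* The competitive comparison is a rank statement about maximal VIs,
  not a formal test of the difference between them.
* With strongly collinear predictors the permute-refit importance of a
  single column is attenuated by its correlated neighbours (the refit
  partially compensates); this is a property of the estimand itself
  and the reason global indices can dominate individually weak cells.
* Low-R nulls trade power for cost: with R = 8 the smallest attainable
  p is bounded by the t_{7} tail, so genuinely strong effects may need
  larger R to reach conventional significance levels.
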