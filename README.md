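# cmtiming

Type- and timing-resolved analysis of childhood maltreatment (CM) and
adult psychopathology, built for researchers studying *when* and *what
kind* of maltreatment matters most — e.g. in high-risk cohorts such as
young adults with a history of residential youth care.

Retrospective instruments like the MACE (Maltreatment and Abuse
Chronology of Exposure) record, for each of ten maltreatment subscales,
a weighted severity score for every life year from 1 to 18.  Asking
which type-by-year exposure best predicts adult mental-health outcomes
means screening dozens of highly collinear predictors — hopeless for
linear-model inference, and exactly the regime this package addresses.

## The method

1. **Chronology scoring.**  The ten subscales are collapsed into four
   CM types — parental abuse (ABUSE), neglect (NEGLECT), peer violence
   (PEER), sexual abuse (SEXA) — each scored 0–10 per life year, ages
   3–18 (ages 1–2 are dropped as unreliable: infantile amnesia).  Three
   global burden indices complement them: SEVERITY (summed subscale
   severity, 0–100), MULTI (number of subscales above threshold, 0–10)
   and DURATION (years with any above-threshold exposure, 0–18).  With
   sex and age this yields a 69-column predictor matrix.

2. **Permute-refit variable importance.**  For a continuous outcome *y*
   (ASEBA-style T-scores: total, internalizing, externalizing) a random
   forest is trained on 75 % of subjects and evaluated on the held-out
   25 %.  The importance of predictor *j* is

   VI_j = MSE_test(forest refit with column *j* permuted) − MSE_test(intact forest),

   averaged over repeated random splits.  Permuting and *refitting*
   (rather than permuting alone) measures the predictor's contribution
   to out-of-sample fit in the presence of its correlated neighbours.

3. **Reshuffled-outcome null.**  Significance comes from an empirical
   null: the outcome vector is reshuffled across subjects and the whole
   importance procedure is rerun, giving per-predictor chance moments
   (null mean, null SD) and a one-sided test of
   z = (VI − null mean)/null SD.  Global burden is then *competitively*
   compared against the best type-by-age cell, and the strongest
   significant predictor per CM type is selected.

4. **Diagnosis validation.**  Selected predictors are validated against
   interview-based disorder status (ICD-10 F-codes grouped into HiTOP
   internalizing/externalizing spectra) with binomial GLMs controlling
   for sex and age; ORs are per SD of the predictor.

Because cohort data of this kind are protected, the package ships a
synthetic cohort generator (`cmtiming.synthetic`) reproducing the
relevant structure — within-subscale year-to-year persistence,
cross-subscale co-occurrence via a Gaussian copula, realistic
prevalence profiles, planted outcome effects — so the entire pipeline
is testable end to end.  See `docs/methods.md` for the model details
and the scaled-down study sizes used in tests.

## Worked example

```python
from cmtiming import (ForestConfig, SyntheticSpec, attach_significance,
                      build_null, competitive_compare, estimate_vi,
                      generate_cohort)

# cohort with a planted early-abuse effect on top of global burden
spec = SyntheticSpec(n_subjects=500, noise_sd=10.0, seed=4000,
                     effect_map=[("SEVERITY", 4.0), ("ABUSE_03", 8.0)])
cohort = generate_cohort(spec)
config = ForestConfig(n_trees=20, max_depth=6, n_split_reps=6, seed=4000)
summary, per_rep = estimate_vi(cohort["predictors"],
                               cohort["outcomes"]["t_total"].to_numpy(), config)
comp = competitive_compare(summary)
print(comp["verdict"], comp["winner"],
      round(comp["best_specific_vi"], 2), round(comp["best_global_vi"], 2))
```

prints

```
specific ABUSE_03 19.75 3.9
```

i.e. permuting-and-refitting the parental-abuse-at-age-3 column costs
19.75 T-score-variance units of test MSE — five times the cost of
breaking the strongest global index (SEVERITY, 3.90) — so the
timing-specific description of maltreatment out-predicts global burden
for this cohort, which is exactly how the effect was planted.  With the
planted timing weight lowered to 0.5 the same code prints
`global SEVERITY 1.08 2.89`: the verdict flips.

The same analysis as a shell session:

```bash
cmtiming simulate --n 400 --seed 0 --out results/cohort
cmtiming score --exposures results/cohort/exposures.csv \
               --subjects results/cohort/subjects.csv --out predictors.csv
cmtiming importance --predictors predictors.csv \
                    --outcomes-file results/cohort/outcomes.csv --outcome total \
                    --reps 10 --trees 30
cmtiming calibrate --predictors predictors.csv \
                   --outcomes-file results/cohort/outcomes.csv --outcome total \
                   --vi-raw vi_raw.csv --null-reps 10 --reps 10 --trees 30
```

The numbered drivers under `analysis/` run the same stages as a
narrative sequence (simulate → score → importance → calibrate →
validate), writing their tables under `results/`.

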