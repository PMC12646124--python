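"""Diagnosis-level validation and descriptive contrasts.

Each predictor selected by the importance analysis (plus the three
global indices) enters a binomial GLM for the matching HiTOP disorder
indicator, controlling for sex and age; odds ratios are per SD of the
predictor.  Also reports the Welch-t / Cohen's-d contrasts of T-scores
between diagnostic groups.

Writes results/glm_results.csv and results/descriptives.csv.
"""

from pathlib import Path

import pandas as pd

from cmtiming.pipeline import OUTCOME_COLUMNS
from cmtiming.subscales import GLOBAL_INDICES
from cmtiming.validation import describe_groups, fit_disorder_glm

ROOT = Path(__file__).resolve().parents[1] / "results"

X = pd.read_csv(ROOT / "predictors.csv").set_index("subject_id")
outcomes = pd.read_csv(ROOT / "cohort" / "outcomes.csv").set_index("subject_id")
selected = pd.read_csv(ROOT / "selected_predictors.csv")

rows = []
for outcome, (_, dx_col) in OUTCOME_COLUMNS.items():
    picks = selected.loc[selected["outcome"] == outcome, "predictor"].tolist()
    data = X.join(outcomes[dx_col]).reset_index(drop=True)
    for pred in dict.fromkeys(picks + list(GLOBAL_INDICES)):
        try:
            fit = fit_disorder_glm(data, pred, dx_col)
        except ValueError as err:
            print(f"  skipped {pred} for {dx_col}: {err}")
            continue
        rows.append({"outcome": outcome, "diagnosis": dx_col, "predictor": pred,
                     "beta": fit.beta, "se": fit.se, "or": fit.or_, "p": fit.p})

glm = pd.DataFrame(rows)
glm.to_csv(ROOT / "glm_results.csv", index=False)
print("binomial GLMs (OR per SD, controlling for sex and age):")
print(glm.round(3).to_string(index=False))

desc = describe_groups(outcomes.reset_index())
desc.to_csv(ROOT / "descriptives.csv", index=False)
print("\nT-score contrasts between diagnostic groups:")
print(desc[["t_score", "diagnosis", "n_without", "n_with", "t", "df", "cohen_d"]]
      .round(2).to_string(index=False))
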