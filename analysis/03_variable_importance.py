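"""Permute-refit variable importance for the three outcomes.

For overall, internalizing and externalizing problems, fits the tree
ensemble on repeated random 75/25 splits and measures each predictor's
importance as the test-MSE increase after permuting its column and
refitting.  Split repetitions and ensemble size are scaled down from
the study configuration (100 repetitions, 500 trees) to desk scale;
both are recorded in the output.

Writes results/vi_raw_<outcome>.csv (per-repetition dMSE) and
results/vi_summary_<outcome>.csv; prints each outcome's strongest
type-by-age and global predictors.
"""

from pathlib import Path

import pandas as pd

from cmtiming.forest import ForestConfig, estimate_vi
from cmtiming.pipeline import OUTCOME_COLUMNS, outcome_seed
from cmtiming.subscales import GLOBAL_INDICES, parse_type_age

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 0
REPS, TREES = 10, 30

X = pd.read_csv(ROOT / "predictors.csv").set_index("subject_id")
outcomes = pd.read_csv(ROOT / "cohort" / "outcomes.csv").set_index("subject_id")

for outcome, (t_col, _) in OUTCOME_COLUMNS.items():
    config = ForestConfig(
        n_trees=TREES, max_depth=6, n_split_reps=REPS, seed=outcome_seed(SEED, outcome)
    )
    summary, per_rep = estimate_vi(X, outcomes.loc[X.index, t_col].to_numpy(), config)
    raw = per_rep.stack().rename("delta_mse").reset_index()
    raw.columns = ["rep", "predictor", "delta_mse"]
    raw.to_csv(ROOT / f"vi_raw_{outcome}.csv", index=False)
    summary.to_csv(ROOT / f"vi_summary_{outcome}.csv")

    vi = summary["vi_mean"]
    specific = vi[[p for p in vi.index if parse_type_age(p)]]
    print(f"{outcome:>14}: best type-age {specific.idxmax()} (VI {specific.max():.2f}); "
          f"best global {vi[list(GLOBAL_INDICES)].idxmax()} "
          f"(VI {vi[list(GLOBAL_INDICES)].max():.2f})")
print(f"\nwrote raw and summary VI tables to {ROOT} (reps={REPS}, trees={TREES})")
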