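"""Score the cohort's chronologies into the forest predictor matrix.

Collapses the ten subscales into the four maltreatment types per age
(3-18, infancy excluded), computes the global burden indices
SEVERITY / MULTI / DURATION, and attaches the sex and age covariates —
the 69-column matrix the importance analysis consumes.

Writes results/predictors.csv; prints range checks and the correlation
of the global indices with the T-score outcomes.
"""

from pathlib import Path

import pandas as pd

from cmtiming.scoring import build_predictor_matrix
from cmtiming.validation import pearson_matrix

ROOT = Path(__file__).resolve().parents[1] / "results"
exposures = pd.read_csv(ROOT / "cohort" / "exposures.csv")
subjects = pd.read_csv(ROOT / "cohort" / "subjects.csv")
outcomes = pd.read_csv(ROOT / "cohort" / "outcomes.csv").set_index("subject_id")

matrix = build_predictor_matrix(exposures, subjects)
matrix.to_csv(ROOT / "predictors.csv", index_label="subject_id")

type_age = matrix.iloc[:, :64]
print(f"predictor matrix: {matrix.shape[0]} subjects x {matrix.shape[1]} columns "
      "(64 type-age + 3 global + 2 covariates)")
print(f"type-age scores in [{type_age.min().min():.2f}, {type_age.max().max():.2f}]")
print("global index ranges:",
      {c: (round(matrix[c].min(), 1), round(matrix[c].max(), 1))
       for c in ("SEVERITY", "MULTI", "DURATION")})

corr = pearson_matrix(
    matrix[["SEVERITY", "MULTI", "DURATION"]],
    outcomes[["t_total", "t_internalizing", "t_externalizing"]],
)
print("\nglobal burden vs outcomes (Pearson r):")
print(corr.loc[["SEVERITY", "MULTI", "DURATION"],
               ["t_total", "t_internalizing", "t_externalizing"]].round(2))
corr.to_csv(ROOT / "correlations.csv")
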