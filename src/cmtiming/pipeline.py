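"""End-to-end orchestration of the maltreatment-timing analysis.

A single :func:`run_pipeline` call takes a cohort (simulated or loaded
from CSV), scores it into the predictor matrix, estimates variable
importance for each requested outcome, calibrates significance against
the reshuffled-outcome null, runs the competitive global-vs-specific
comparison, validates selected predictors against diagnosis status with
binomial GLMs, and writes every table plus a manifest that allows a
bit-identical rerun.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    attach_significance,
    build_null,
    competitive_compare,
    config_hash,
    select_top_per_type,
)
from .forest import ForestConfig, estimate_vi
from .scoring import ThresholdTable, build_predictor_matrix, prevalence_by_age
from .subscales import GLOBAL_INDICES, parse_type_age
from .synthetic import SyntheticSpec, generate_cohort
from .validation import describe_groups, fit_disorder_glm, pearson_matrix

__all__ = ["RunConfig", "run_pipeline", "render_vi_profile"]

OUTCOME_COLUMNS = {
    "total": ("t_total", "dx_any"),
    "internalizing": ("t_internalizing", "dx_internalizing"),
    "externalizing": ("t_externalizing", "dx_externalizing"),
}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Reproducible description of one full analysis run."""

    seed: int = 0
    simulate: SyntheticSpec | None = None
    subjects_path: str | None = None
    exposures_path: str | None = None
    outcomes_path: str | None = None
    forest: ForestConfig = dataclasses.field(default_factory=ForestConfig)
    thresholds: ThresholdTable = dataclasses.field(default_factory=ThresholdTable)
    n_null_reps: int = 40
    null_split_reps: int | None = None
    alpha: float = 0.05
    outcomes: tuple[str, ...] = ("total", "internalizing", "externalizing")

    def __post_init__(self) -> None:
        bad = set(self.outcomes) - set(OUTCOME_COLUMNS)
        if bad:
            raise ValueError(
                f"unknown outcome(s) {sorted(bad)}; valid choices: "
                f"{sorted(OUTCOME_COLUMNS)}"
            )
        if self.simulate is None:
            for field in ("subjects_path", "exposures_path", "outcomes_path"):
                path = getattr(self, field)
                if path is None:
                    raise ValueError(f"{field} is required when not simulating")
                if not Path(path).exists():
                    raise ValueError(f"{field}: file not found: {path}")


def outcome_seed(master_seed: int, outcome: str) -> int:
    """Per-outcome engine seed: a counter offset from the master seed.

    The offset is the outcome's fixed position in the canonical ordering,
    so adding or reordering requested outcomes never perturbs another
    outcome's stream.
    """
    index = list(OUTCOME_COLUMNS).index(outcome)
    return int(np.random.default_rng([int(master_seed), 10 + index]).integers(2**31))


def render_vi_profile(vi_table: pd.DataFrame) -> pd.DataFrame:
    """Tidy long-format VI profile: one row per predictor.

    Type-by-age predictors carry their type and age; global indices and
    covariates are carried as age-invariant reference rows, matching the
    layout used for importance-by-age profile figures.
    """
    rows = []
    for name, row in vi_table.iterrows():
        parsed = parse_type_age(name)
        kind = (
            "type_age" if parsed else "global" if name in GLOBAL_INDICES else "covariate"
        )
        rows.append(
            {
                "predictor": name,
                "kind": kind,
                "cm_type": parsed[0] if parsed else None,
                "age": parsed[1] if parsed else None,
                "vi_mean": row["vi_mean"],
                "z": row.get("z", np.nan),
                "p": row.get("p", np.nan),
                "significant": bool(row.get("significant", False)),
            }
        )
    return pd.DataFrame(rows)


def _load_cohort(config: RunConfig, out_dir: Path) -> dict[str, pd.DataFrame]:
    if config.simulate is not None:
        cohort = generate_cohort(config.simulate, config.thresholds)
    else:
        subjects = pd.read_csv(config.subjects_path)
        exposures = pd.read_csv(config.exposures_path)
        outcomes = pd.read_csv(config.outcomes_path)
        predictors = build_predictor_matrix(exposures, subjects, config.thresholds)
        cohort = {
            "subjects": subjects,
            "exposures": exposures,
            "predictors": predictors,
            "outcomes": outcomes,
        }
    cohort["subjects"].to_csv(out_dir / "subjects.csv", index=False)
    cohort["exposures"].to_csv(out_dir / "exposures.csv", index=False)
    cohort["outcomes"].to_csv(out_dir / "outcomes.csv", index=False)
    cohort["predictors"].to_csv(out_dir / "predictors.csv", index_label="subject_id")
    return cohort


def run_pipeline(config: RunConfig, out_dir: str | Path, log=print) -> dict:
    """Execute the full analysis; returns a dict of in-memory results.

    Writes, under ``out_dir``: the cohort tables, one
    ``vi_table_<outcome>.csv`` and ``vi_profile_<outcome>.csv`` per
    outcome, ``competitive.csv``, ``selected_predictors.csv``,
    ``glm_results.csv``, ``descriptives.csv``, ``correlations.csv``,
    ``prevalence_by_age.csv`` and ``manifest.json``.  Reruns with an
    identical config produce byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log(f"[{name}]")

    stage("cohort")
    cohort = _load_cohort(config, out_dir)
    predictors, outcomes_df = cohort["predictors"], cohort["outcomes"]
    outcomes_df = outcomes_df.set_index("subject_id").loc[predictors.index].reset_index()

    prevalence_by_age(cohort["exposures"], config.thresholds).to_csv(
        out_dir / "prevalence_by_age.csv"
    )

    results: dict = {"vi_tables": {}, "competitive": {}, "selected": {}}
    comp_rows, sel_rows, glm_rows = [], [], []
    for outcome in config.outcomes:
        t_col, dx_col = OUTCOME_COLUMNS[outcome]
        y = outcomes_df[t_col].to_numpy()
        fc = dataclasses.replace(config.forest, seed=outcome_seed(config.seed, outcome))
        stage(f"importance:{outcome} ({fc.n_split_reps} split reps)")
        summary, per_rep = estimate_vi(predictors, y, fc)
        stage(f"null:{outcome} ({config.n_null_reps} reshuffles)")
        null = build_null(
            predictors, y, fc,
            n_null_reps=config.n_null_reps,
            null_split_reps=config.null_split_reps,
        )
        table = attach_significance(
            summary, null, per_rep=per_rep, alpha=config.alpha, config=fc
        )
        table.to_csv(out_dir / f"vi_table_{outcome}.csv", index_label="predictor")
        render_vi_profile(table).to_csv(out_dir / f"vi_profile_{outcome}.csv", index=False)
        results["vi_tables"][outcome] = table

        comp = competitive_compare(table)
        comp_rows.append({"outcome": outcome, **comp})
        results["competitive"][outcome] = comp

        selected = select_top_per_type(table)
        results["selected"][outcome] = selected
        for cm_type, pred in sorted(selected.items()):
            sel_rows.append(
                {
                    "outcome": outcome, "cm_type": cm_type, "predictor": pred,
                    "vi_mean": table.loc[pred, "vi_mean"], "p": table.loc[pred, "p"],
                }
            )

        stage(f"glm:{outcome}")
        data = predictors.join(outcomes_df.set_index("subject_id")[dx_col])
        candidates = list(dict.fromkeys(list(selected.values()) + list(GLOBAL_INDICES)))
        for pred in candidates:
            try:
                fit = fit_disorder_glm(data.reset_index(drop=True), pred, dx_col)
            except ValueError as err:
                log(f"  glm skipped for {pred}: {err}")
                continue
            glm_rows.append(
                {
                    "outcome": outcome, "diagnosis": dx_col, "predictor": pred,
                    "beta": fit.beta, "se": fit.se, "or": fit.or_, "p": fit.p,
                    "n": fit.n, "warning": fit.warning or "",
                }
            )

    pd.DataFrame(comp_rows).to_csv(out_dir / "competitive.csv", index=False)
    pd.DataFrame(sel_rows).to_csv(out_dir / "selected_predictors.csv", index=False)
    glm_table = pd.DataFrame(glm_rows)
    glm_table.to_csv(out_dir / "glm_results.csv", index=False)
    results["glm"] = glm_table

    stage("descriptives")
    descriptives = describe_groups(outcomes_df)
    descriptives.to_csv(out_dir / "descriptives.csv", index=False)
    results["descriptives"] = descriptives
    corr_cols = list(GLOBAL_INDICES)
    t_cols = [OUTCOME_COLUMNS[o][0] for o in config.outcomes]
    pearson_matrix(
        predictors[corr_cols], outcomes_df.set_index("subject_id")[t_cols]
    ).to_csv(out_dir / "correlations.csv")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "n_null_reps": config.n_null_reps,
        "null_split_reps": config.null_split_reps,
        "outcomes": list(config.outcomes),
        "forest": dataclasses.asdict(config.forest),
        "forest_config_hash": config_hash(config.forest),
        "thresholds": {k: float(v) for k, v in config.thresholds.values.items()},
        "simulate": config.simulate.to_dict() if config.simulate else None,
        "inputs": {
            "subjects": config.subjects_path,
            "exposures": config.exposures_path,
            "outcomes": config.outcomes_path,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
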