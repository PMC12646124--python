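"""Scoring of maltreatment chronologies into the predictor set.

A chronology records, per subject, a weighted severity score in [0, 10]
for each of the ten MACE subscales in each life year 1-18.  This module
turns a cohort of chronologies into the predictor matrix used by the
variable-importance analysis:

* 64 type-by-age predictors (ABUSE/NEGLECT/PEER/SEXA, ages 3-18), each a
  weighted score in [0, 10];
* three global burden indices — SEVERITY (summed subscale severity,
  0-100), MULTI (number of subscales above threshold, 0-10) and DURATION
  (number of years with any above-threshold exposure, 0-18);
* the covariates sex and age.

Ages 1-2 are excluded from the type-by-age predictors because
retrospective reports for those years are unreliable (infantile
amnesia); global indices default to the full 1-18 window, configurable.

Cohorts are represented as pandas DataFrames: long format
``(subject_id, subscale, age, score)`` for I/O, and a wide layout with
``(subscale, age)`` MultiIndex columns internally.  A single subject is
simply a one-row wide frame.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np
import pandas as pd
import yaml

from .subscales import (
    AGES_FULL,
    AGES_PREDICTOR,
    CM_TYPES,
    COVARIATES,
    GLOBAL_INDICES,
    SCORE_MAX,
    SUBSCALES,
    TYPE_MAP,
    type_age_column,
    type_age_columns,
)

__all__ = [
    "ThresholdTable",
    "long_to_wide",
    "wide_to_long",
    "aggregate_to_types",
    "exclude_infantile_years",
    "subscale_overall",
    "compute_severity",
    "compute_multiplicity",
    "compute_duration",
    "prevalence_by_age",
    "build_predictor_matrix",
]


@dataclasses.dataclass(frozen=True)
class ThresholdTable:
    """Per-subscale severity thresholds on the 0-10 scale.

    A subscale-year (or a subscale overall) counts as *exposed above
    threshold* when its weighted score strictly exceeds the subscale's
    threshold.  Validation studies supply instrument-specific values; the
    default places every threshold at 0.5, i.e. any non-trivial endorsement
    counts.
    """

    values: pd.Series = dataclasses.field(
        default_factory=lambda: pd.Series(0.5, index=list(SUBSCALES))
    )

    def __post_init__(self) -> None:
        vals = pd.Series(self.values, dtype=float)
        missing = set(SUBSCALES) - set(vals.index)
        if missing:
            raise ValueError(f"ThresholdTable missing subscales: {sorted(missing)}")
        extra = set(vals.index) - set(SUBSCALES)
        if extra:
            raise ValueError(f"ThresholdTable has unknown subscales: {sorted(extra)}")
        if ((vals < 0) | (vals > SCORE_MAX)).any():
            raise ValueError("ThresholdTable values must lie in [0, 10]")
        object.__setattr__(self, "values", vals.reindex(list(SUBSCALES)))

    @classmethod
    def uniform(cls, threshold: float = 0.5) -> "ThresholdTable":
        return cls(pd.Series(float(threshold), index=list(SUBSCALES)))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ThresholdTable":
        return cls(pd.Series(dict(mapping), dtype=float))

    @classmethod
    def from_yaml(cls, path) -> "ThresholdTable":
        """Load published thresholds from a ``subscale: value`` YAML file."""
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def _check_scores(values: np.ndarray) -> None:
    if not np.isfinite(values).all():
        raise ValueError("exposure scores must be finite")
    if (values < 0).any() or (values > SCORE_MAX).any():
        raise ValueError("exposure scores must lie in [0, 10]")


def long_to_wide(exposures: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long exposure table to subjects x (subscale, age).

    The long table has columns ``subject_id, subscale, age, score``.
    Missing subscale/age cells are filled with 0 (no reported exposure);
    the output always carries the complete 10 x 18 column grid.
    """
    required = {"subject_id", "subscale", "age", "score"}
    missing = required - set(exposures.columns)
    if missing:
        raise ValueError(f"exposure table missing columns: {sorted(missing)}")
    unknown = set(exposures["subscale"].unique()) - set(SUBSCALES)
    if unknown:
        raise ValueError(f"unknown subscale labels: {sorted(unknown)}")
    bad_age = set(exposures["age"].unique()) - set(AGES_FULL)
    if bad_age:
        raise ValueError(f"ages outside 1-18: {sorted(bad_age)}")
    _check_scores(exposures["score"].to_numpy(dtype=float))
    wide = exposures.pivot_table(
        index="subject_id", columns=["subscale", "age"], values="score", aggfunc="sum"
    )
    full = pd.MultiIndex.from_product(
        [list(SUBSCALES), list(AGES_FULL)], names=["subscale", "age"]
    )
    wide = wide.reindex(columns=full).fillna(0.0)
    _check_scores(wide.to_numpy())  # duplicate rows could overflow the scale
    return wide


def wide_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`long_to_wide`; zero cells are kept explicit."""
    long = wide.stack(["subscale", "age"], future_stack=True).rename("score").reset_index()
    long.columns = ["subject_id", "subscale", "age", "score"]
    return long


def aggregate_to_types(wide: pd.DataFrame, rule: str = "mean") -> pd.DataFrame:
    """Collapse the ten subscales into the four CM types, per age.

    The default rule averages the constituent subscale scores of each
    type within a year, which keeps every type-year score on the common
    [0, 10] scale and lets every subscale contribute; ``rule="max"``
    takes the worst constituent instead.
    """
    if rule not in ("mean", "max"):
        raise ValueError(f"unknown aggregation rule: {rule!r}")
    unknown = set(wide.columns.get_level_values("subscale")) - set(SUBSCALES)
    if unknown:
        raise ValueError(f"unknown subscale labels: {sorted(unknown)}")
    blocks = {}
    for cm_type, members in TYPE_MAP.items():
        sub = wide.loc[:, wide.columns.get_level_values("subscale").isin(members)]
        grouped = sub.T.groupby(level="age")
        block = (grouped.mean() if rule == "mean" else grouped.max()).T
        blocks[cm_type] = block
    out = pd.concat(blocks, axis=1, names=["cm_type", "age"])
    return out


def exclude_infantile_years(frame: pd.DataFrame) -> pd.DataFrame:
    """Drop ages 1-2 from a wide (by-subscale or by-type) frame.

    Idempotent: frames already restricted to ages 3-18 pass through
    unchanged.
    """
    ages = frame.columns.get_level_values("age")
    return frame.loc[:, ~ages.isin([1, 2])]


def subscale_overall(wide: pd.DataFrame) -> pd.DataFrame:
    """Per-subject overall severity of each subscale: the peak year score."""
    return wide.T.groupby(level="subscale").max().T.reindex(columns=list(SUBSCALES))


def compute_severity(wide: pd.DataFrame) -> pd.Series:
    """SEVERITY: summed overall severity across the ten subscales (0-100)."""
    return subscale_overall(wide).sum(axis=1).rename("SEVERITY")


def compute_multiplicity(wide: pd.DataFrame, thresholds: ThresholdTable) -> pd.Series:
    """MULTI: number of subscales whose overall severity exceeds threshold (0-10)."""
    overall = subscale_overall(wide)
    return (overall > thresholds.values).sum(axis=1).rename("MULTI")


def compute_duration(wide: pd.DataFrame, thresholds: ThresholdTable) -> pd.Series:
    """DURATION: number of years with any above-threshold subscale exposure (0-18)."""
    thr = thresholds.values.reindex(wide.columns.get_level_values("subscale")).to_numpy()
    above = wide.to_numpy() > thr
    ages = wide.columns.get_level_values("age").to_numpy()
    any_by_age = pd.DataFrame(above, index=wide.index, columns=ages).T.groupby(level=0).any().T
    return any_by_age.sum(axis=1).rename("DURATION")


def prevalence_by_age(
    exposures: pd.DataFrame, thresholds: ThresholdTable | None = None
) -> pd.DataFrame:
    """Proportion of subjects exposed above threshold, per CM type and age.

    Accepts a long exposure table or a wide by-subscale frame.  A subject
    counts as exposed to a type at an age if any constituent subscale-year
    score exceeds its threshold.
    """
    if thresholds is None:
        thresholds = ThresholdTable()
    wide = exposures if isinstance(exposures.columns, pd.MultiIndex) else long_to_wide(exposures)
    if len(wide) == 0:
        raise ValueError("prevalence_by_age: empty cohort")
    thr = thresholds.values.reindex(wide.columns.get_level_values("subscale")).to_numpy()
    above = pd.DataFrame(wide.to_numpy() > thr, index=wide.index, columns=wide.columns)
    rows = {}
    for cm_type, members in TYPE_MAP.items():
        sub = above.loc[:, above.columns.get_level_values("subscale").isin(members)]
        rows[cm_type] = sub.T.groupby(level="age").any().T.mean(axis=0)
    return pd.DataFrame(rows).T.reindex(index=list(CM_TYPES))


def build_predictor_matrix(
    exposures: pd.DataFrame,
    subjects: pd.DataFrame | None = None,
    thresholds: ThresholdTable | None = None,
    global_age_window: tuple[int, int] = (1, 18),
    aggregation: str = "mean",
) -> pd.DataFrame:
    """Assemble the full predictor matrix for the forest analysis.

    Columns: 64 type-by-age scores (``ABUSE_03`` ... ``SEXA_18``), the
    three global indices, and — when a subject table with ``sex`` and
    ``age`` is supplied — the two covariates (69 columns total).

    Type-by-age predictors always use ages 3-18; the global indices are
    computed over ``global_age_window`` (default: the full 1-18 record,
    since dropping infancy years is only required of the per-year
    predictors).
    """
    if thresholds is None:
        thresholds = ThresholdTable()
    wide = exposures if isinstance(exposures.columns, pd.MultiIndex) else long_to_wide(exposures)
    lo, hi = global_age_window
    if not (1 <= lo <= hi <= 18):
        raise ValueError(f"global_age_window out of range: {global_age_window}")
    by_type = exclude_infantile_years(aggregate_to_types(wide, rule=aggregation))
    cols = {}
    for cm_type in CM_TYPES:
        for age in AGES_PREDICTOR:
            cols[type_age_column(cm_type, age)] = by_type[(cm_type, age)]
    window = wide.loc[:, wide.columns.get_level_values("age").isin(range(lo, hi + 1))]
    matrix = pd.DataFrame(cols, index=wide.index)
    matrix["SEVERITY"] = compute_severity(window)
    matrix["MULTI"] = compute_multiplicity(window, thresholds)
    matrix["DURATION"] = compute_duration(window, thresholds)
    if subjects is not None:
        sub = subjects.set_index("subject_id") if "subject_id" in subjects.columns else subjects
        missing = {"sex", "age"} - set(sub.columns)
        if missing:
            raise ValueError(f"subject table missing columns: {sorted(missing)}")
        matrix = matrix.join(sub[["sex", "age"]], how="left")
        if matrix[["sex", "age"]].isna().any().any():
            raise ValueError("subject table does not cover all subjects in the exposures")
    return matrix


def predictor_columns(with_covariates: bool = True) -> list[str]:
    """Canonical predictor ordering: 64 type-age + 3 global (+ sex, age)."""
    cols = type_age_columns() + list(GLOBAL_INDICES)
    if with_covariates:
        cols += list(COVARIATES)
    return cols
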