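"""Constants shared across the package: MACE subscales, CM types, age grid.

The MACE (Maltreatment and Abuse Chronology of Exposure) instrument yields
ten maltreatment subscales, each recorded retrospectively for every life
year from 1 to 18.  For interpretability the ten subscales are collapsed
into four maltreatment types: parental abuse (ABUSE), parental neglect
(NEGLECT), peer violence (PEER), and sexual abuse (SEXA).
"""

from __future__ import annotations

# The ten MACE subscales, in canonical order.
SUBSCALES: tuple[str, ...] = (
    "parental_physical_abuse",
    "parental_verbal_abuse",
    "parental_nonverbal_abuse",
    "witnessed_violence_parents",
    "witnessed_violence_siblings",
    "emotional_neglect",
    "physical_neglect",
    "peer_emotional",
    "peer_physical",
    "sexual_abuse",
)

# Fixed subscale -> type mapping.
TYPE_MAP: dict[str, tuple[str, ...]] = {
    "ABUSE": (
        "parental_physical_abuse",
        "parental_verbal_abuse",
        "parental_nonverbal_abuse",
        "witnessed_violence_parents",
        "witnessed_violence_siblings",
    ),
    "NEGLECT": ("emotional_neglect", "physical_neglect"),
    "PEER": ("peer_emotional", "peer_physical"),
    "SEXA": ("sexual_abuse",),
}

CM_TYPES: tuple[str, ...] = tuple(TYPE_MAP)

# Full retrospective age grid and the predictor window.  Ages 1-2 are
# retained in the raw chronology but dropped from the predictor matrix
# (infantile-amnesia exclusion); global indices use the full grid by
# default.
AGES_FULL: tuple[int, ...] = tuple(range(1, 19))
AGES_PREDICTOR: tuple[int, ...] = tuple(range(3, 19))

#: Maximum weighted severity of a subscale-year score.
SCORE_MAX: float = 10.0

GLOBAL_INDICES: tuple[str, ...] = ("SEVERITY", "MULTI", "DURATION")
COVARIATES: tuple[str, ...] = ("sex", "age")


def type_age_column(cm_type: str, age: int) -> str:
    """Canonical predictor-column name for a type/age cell, e.g. ``ABUSE_03``."""
    return f"{cm_type}_{age:02d}"


def type_age_columns() -> list[str]:
    """All 64 type-by-age predictor names, type-major, ages 3-18."""
    return [type_age_column(t, a) for t in CM_TYPES for a in AGES_PREDICTOR]


def parse_type_age(column: str) -> tuple[str, int] | None:
    """Invert :func:`type_age_column`; ``None`` for non type-age columns."""
    head, _, tail = column.rpartition("_")
    if head in CM_TYPES and tail.isdigit():
        return head, int(tail)
    return None
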