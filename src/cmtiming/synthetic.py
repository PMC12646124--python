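"""Synthetic cohort generator.

The study population this package targets — young adults with a history
of residential youth care — cannot be redistributed, so every stage of
the pipeline is exercised on synthetic cohorts that reproduce the
statistical structure the analysis has to cope with:

* ten maltreatment subscales recorded per life year 1-18, with strong
  year-to-year persistence within a subscale and cross-subscale
  co-occurrence (induced by a Gaussian copula on year-level latents);
* prevalence profiles in which neglect is near ceiling, sexual abuse is
  rare throughout, and peer violence is rare before school age;
* continuous outcomes on the ASEBA T-score scale (population mean 50,
  SD 10) driven by configurable planted effects on type-by-age cells
  and/or global burden indices, plus Gaussian noise;
* binary diagnosis indicators generated from the same linear predictor
  through a logistic link.

Exposure dynamics within a subscale follow a two-state Markov chain
whose marginals track the target prevalence curve: with persistence
``r`` the probability of remaining exposed from one year to the next is
``p_t + r * (1 - p_t)``, so ``r = 0`` recovers independent years and
``r = 1`` makes exposure absorbing.  Cross-subscale dependence enters
through the copula correlation of the per-year innovation uniforms.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, ndtr

from . import scoring
from .subscales import AGES_FULL, SCORE_MAX, SUBSCALES, type_age_column

__all__ = [
    "SeverityModel",
    "SyntheticSpec",
    "default_prevalence",
    "default_co_occurrence",
    "generate_exposures",
    "generate_outcomes",
    "generate_cohort",
]

OUTCOMES: tuple[str, ...] = ("total", "internalizing", "externalizing")


@dataclasses.dataclass(frozen=True)
class SeverityModel:
    """Distribution of the weighted subscale-year score given exposure.

    ``kind="beta"`` draws ``floor + (10 - floor) * Beta(alpha, beta)``;
    the floor (default 0.5, matching the default scoring threshold)
    keeps every realised exposure above threshold, so the prevalence
    curve is simultaneously the above-threshold exposure probability.
    ``kind="fixed"`` returns a constant score, useful for degenerate
    test cases.
    """

    kind: str = "beta"
    alpha: float = 2.0
    beta: float = 5.0
    value: float = SCORE_MAX
    floor: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "fixed"):
            raise ValueError(f"severity_given_exposure: unknown kind {self.kind!r}")
        if self.kind == "beta" and (self.alpha <= 0 or self.beta <= 0):
            raise ValueError("severity_given_exposure: alpha and beta must be positive")
        if not 0 <= self.floor < SCORE_MAX:
            raise ValueError("severity_given_exposure: floor must lie in [0, 10)")
        if self.kind == "fixed" and not 0 <= self.value <= SCORE_MAX:
            raise ValueError("severity_given_exposure: fixed value must lie in [0, 10]")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(size, float(self.value))
        return self.floor + (SCORE_MAX - self.floor) * rng.beta(self.alpha, self.beta, size)


def default_prevalence() -> pd.DataFrame:
    """Per-subscale, per-age exposure probabilities for the default cohort.

    Shaped after the exposure profile of high-risk residential-care
    samples: neglect near ceiling across childhood, parental abuse
    common, peer violence rare before school age and peaking in early
    adolescence, sexual abuse rare (< 10 %) at every age.
    """
    ages = np.asarray(AGES_FULL, dtype=float)
    curves = {
        "parental_physical_abuse": 0.30 + 0.10 * np.exp(-((ages - 8) / 5.0) ** 2),
        "parental_verbal_abuse": 0.45 + 0.10 * np.exp(-((ages - 10) / 6.0) ** 2),
        "parental_nonverbal_abuse": np.full_like(ages, 0.40),
        "witnessed_violence_parents": np.full_like(ages, 0.25),
        "witnessed_violence_siblings": np.full_like(ages, 0.22),
        "emotional_neglect": np.full_like(ages, 0.85),
        "physical_neglect": np.full_like(ages, 0.60),
        "peer_emotional": 0.32 * expit((ages - 7.5) / 1.5) * np.exp(-((ages - 13) / 14) ** 2),
        "peer_physical": 0.22 * expit((ages - 7.5) / 1.5),
        "sexual_abuse": 0.02 + 0.05 * expit((ages - 12) / 2.0),
    }
    frame = pd.DataFrame(curves, index=list(AGES_FULL)).T
    frame.index.name = "subscale"
    frame.columns.name = "age"
    return frame.reindex(list(SUBSCALES))


def default_co_occurrence(within: float = 0.5, between: float = 0.2) -> np.ndarray:
    """Block co-occurrence: higher within a CM type than across types."""
    blocks = {s: t for t, members in scoring.TYPE_MAP.items() for s in members}
    n = len(SUBSCALES)
    mat = np.full((n, n), between)
    for i, a in enumerate(SUBSCALES):
        for j, b in enumerate(SUBSCALES):
            if blocks[a] == blocks[b]:
                mat[i, j] = within
    np.fill_diagonal(mat, 1.0)
    return mat


def _default_effect_map() -> dict[str, list[tuple[str, float]]]:
    # Planted structure echoing the qualitative pattern the pipeline is
    # designed to detect: global burden drives internalizing problems,
    # early parental abuse drives externalizing problems.
    return {
        "total": [("SEVERITY", 2.5), (type_age_column("ABUSE", 6), 1.5),
                  (type_age_column("PEER", 14), 1.2)],
        "internalizing": [("SEVERITY", 3.0), ("MULTI", 2.0),
                          (type_age_column("PEER", 14), 1.2)],
        "externalizing": [(type_age_column("ABUSE", 3), 3.0), ("SEVERITY", 2.0),
                          (type_age_column("PEER", 17), 1.5)],
    }


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Complete generative recipe for one synthetic cohort.

    Parameters
    ----------
    n_subjects:
        Cohort size (>= 2).
    prevalence_curve:
        10 x 18 frame of per-subscale, per-age above-threshold exposure
        probabilities; defaults to :func:`default_prevalence`.
    persistence:
        Probability in [0, 1] that exposure in year *t* continues in
        year *t + 1* beyond what the marginal prevalence implies
        (0 = independent years, 1 = absorbing exposure).
    co_occurrence:
        Symmetric positive-semidefinite 10 x 10 copula correlation with
        unit diagonal, controlling cross-subscale dependence.
    severity_given_exposure:
        :class:`SeverityModel` for the score of an exposed subscale-year.
    effect_map:
        Planted outcome effects: either a single list of
        ``(predictor_name, weight)`` pairs applied to all three T-score
        outcomes, or a mapping from outcome name to such a list.
        Weights act on the outcome (T-score) scale per SD of the
        predictor.
    noise_sd:
        SD of the Gaussian residual added to each T-score.
    logistic_intercept, logistic_slope:
        Diagnosis link: each spectrum indicator is Bernoulli with
        probability ``expit(intercept + slope * lp)`` where ``lp`` is
        that outcome's planted linear predictor.  The intercept may be a
        mapping per spectrum.
    sex_ratio:
        Proportion of female subjects (sex coded 1 = female, 0 = male).
    age_mean, age_sd:
        Adult age at assessment, in years.
    seed:
        Master seed; fixed seed gives bit-identical cohorts.
    """

    n_subjects: int = 400
    prevalence_curve: pd.DataFrame = dataclasses.field(default_factory=default_prevalence)
    persistence: float = 0.85
    co_occurrence: np.ndarray = dataclasses.field(default_factory=default_co_occurrence)
    severity_given_exposure: SeverityModel = dataclasses.field(default_factory=SeverityModel)
    effect_map: Mapping[str, Sequence[tuple[str, float]]] | Sequence[tuple[str, float]] = (
        dataclasses.field(default_factory=_default_effect_map)
    )
    noise_sd: float = 9.0
    logistic_intercept: float | Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"internalizing": -1.0, "externalizing": 0.0}
    )
    logistic_slope: float = 0.25
    sex_ratio: float = 0.40
    age_mean: float = 26.0
    age_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects: must be >= 2")
        prev = pd.DataFrame(self.prevalence_curve, dtype=float)
        if set(prev.index) != set(SUBSCALES) or set(prev.columns) != set(AGES_FULL):
            raise ValueError("prevalence_curve: must cover all 10 subscales and ages 1-18")
        prev = prev.reindex(index=list(SUBSCALES), columns=list(AGES_FULL))
        prev.index.name, prev.columns.name = "subscale", "age"
        if ((prev < 0) | (prev > 1)).any().any() or prev.isna().any().any():
            raise ValueError("prevalence_curve: probabilities must lie in [0, 1]")
        object.__setattr__(self, "prevalence_curve", prev)
        if not 0 <= self.persistence <= 1:
            raise ValueError("persistence: must lie in [0, 1]")
        co = np.asarray(self.co_occurrence, dtype=float)
        if co.shape != (10, 10):
            raise ValueError("co_occurrence: must be 10 x 10")
        if not np.allclose(co, co.T):
            raise ValueError("co_occurrence: must be symmetric")
        if not np.allclose(np.diag(co), 1.0):
            raise ValueError("co_occurrence: must have unit diagonal")
        if np.linalg.eigvalsh(co).min() < -1e-8:
            raise ValueError("co_occurrence: must be positive semidefinite")
        object.__setattr__(self, "co_occurrence", co)
        if self.noise_sd < 0:
            raise ValueError("noise_sd: must be non-negative")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio: must lie in [0, 1]")
        if self.age_sd < 0:
            raise ValueError("age_sd: must be non-negative")

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "n_subjects": self.n_subjects,
            "prevalence_curve": {
                s: [float(v) for v in row] for s, row in self.prevalence_curve.iterrows()
            },
            "persistence": self.persistence,
            "co_occurrence": self.co_occurrence.tolist(),
            "severity_given_exposure": dataclasses.asdict(self.severity_given_exposure),
            "effect_map": (
                {k: [[n, float(w)] for n, w in v] for k, v in self.effect_map.items()}
                if isinstance(self.effect_map, Mapping)
                else [[n, float(w)] for n, w in self.effect_map]
            ),
            "noise_sd": self.noise_sd,
            "logistic_intercept": (
                dict(self.logistic_intercept)
                if isinstance(self.logistic_intercept, Mapping)
                else self.logistic_intercept
            ),
            "logistic_slope": self.logistic_slope,
            "sex_ratio": self.sex_ratio,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticSpec":
        d = dict(d)
        if "prevalence_curve" in d:
            d["prevalence_curve"] = pd.DataFrame(
                {int(a): {s: row[i] for s, row in d["prevalence_curve"].items()}
                 for i, a in enumerate(AGES_FULL)}
            )
        if "co_occurrence" in d:
            d["co_occurrence"] = np.asarray(d["co_occurrence"], dtype=float)
        if "severity_given_exposure" in d and isinstance(d["severity_given_exposure"], Mapping):
            d["severity_given_exposure"] = SeverityModel(**d["severity_given_exposure"])
        if "effect_map" in d and isinstance(d["effect_map"], Mapping):
            d["effect_map"] = {
                k: [(n, float(w)) for n, w in v] for k, v in d["effect_map"].items()
            }
        elif "effect_map" in d:
            d["effect_map"] = [(n, float(w)) for n, w in d["effect_map"]]
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def generate_exposures(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the subject table and the exposure chronologies.

    Returns ``(subjects, exposures)``: a frame with columns
    ``subject_id, sex, age`` and a long exposure frame with columns
    ``subject_id, subscale, age, score``.

    Per subscale, exposure follows the persistence-interpolated Markov
    chain described in the module docstring; each year's innovations
    across the ten subscales are coupled through a Gaussian copula with
    correlation ``spec.co_occurrence``.  Exposed subscale-years receive
    a severity score from ``spec.severity_given_exposure``; unexposed
    cells score 0.
    """
    rng = np.random.default_rng([spec.seed, 0])
    n, k = spec.n_subjects, len(SUBSCALES)
    prev = spec.prevalence_curve.to_numpy()  # (10, 18)
    chol = np.linalg.cholesky(spec.co_occurrence + 1e-10 * np.eye(k))
    r = spec.persistence

    scores = np.zeros((n, k, len(AGES_FULL)))
    exposed_prev = np.zeros((n, k), dtype=bool)
    for ti, _age in enumerate(AGES_FULL):
        z = rng.standard_normal((n, k)) @ chol.T
        u = ndtr(z)
        p_t = prev[:, ti]
        if ti == 0:
            thresh = np.broadcast_to(p_t, (n, k))
        else:
            p_prev = prev[:, ti - 1]
            stay = p_t + r * (1.0 - p_t)
            with np.errstate(divide="ignore", invalid="ignore"):
                onset = np.where(
                    p_prev < 1.0, (p_t - stay * p_prev) / (1.0 - p_prev), 0.0
                )
            onset = np.clip(onset, 0.0, 1.0)
            thresh = np.where(exposed_prev, stay, onset)
        exposed = u < thresh
        n_exp = int(exposed.sum())
        if n_exp:
            scores[:, :, ti][exposed] = spec.severity_given_exposure.draw(rng, n_exp)
        exposed_prev = exposed

    subjects = pd.DataFrame(
        {
            "subject_id": np.arange(1, n + 1),
            "sex": (rng.random(n) < spec.sex_ratio).astype(int),
            "age": np.round(rng.normal(spec.age_mean, spec.age_sd, n), 1),
        }
    )
    long = pd.DataFrame(
        {
            "subject_id": np.repeat(subjects["subject_id"].to_numpy(), k * 18),
            "subscale": np.tile(np.repeat(list(SUBSCALES), 18), n),
            "age": np.tile(list(AGES_FULL), n * k),
            "score": scores.reshape(-1),
        }
    )
    return subjects, long


def _resolve_effects(
    effect_map, predictors: pd.DataFrame
) -> dict[str, list[tuple[str, float]]]:
    if not isinstance(effect_map, Mapping):
        effect_map = {o: list(effect_map) for o in OUTCOMES}
    resolved: dict[str, list[tuple[str, float]]] = {}
    for outcome in OUTCOMES:
        pairs = [(str(n), float(w)) for n, w in effect_map.get(outcome, [])]
        unknown = [n for n, _ in pairs if n not in predictors.columns]
        if unknown:
            raise ValueError(
                f"effect_map[{outcome!r}]: unknown predictor(s) {unknown}; "
                f"valid names are {list(predictors.columns)}"
            )
        resolved[outcome] = pairs
    return resolved


def generate_outcomes(
    exposures: pd.DataFrame,
    spec: SyntheticSpec,
    subjects: pd.DataFrame | None = None,
    predictors: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw T-score outcomes and diagnosis indicators for a cohort.

    Each of the three T-score outcomes is ``50 + sum_j w_j * z_j +
    Normal(0, noise_sd)`` where ``z_j`` is the cohort-standardised
    planted predictor.  Spectrum diagnoses are Bernoulli draws from a
    logistic link on the same linear predictor; ``dx_any`` is their
    union, matching the definition used for the interview outcomes.
    """
    if predictors is None:
        predictors = scoring.build_predictor_matrix(exposures, subjects)
    effects = _resolve_effects(spec.effect_map, predictors)
    rng = np.random.default_rng([spec.seed, 1])
    n = len(predictors)

    std = predictors.std(axis=0, ddof=0)
    centred = predictors - predictors.mean(axis=0)
    zscored = centred.divide(std.where(std > 0, np.inf), axis=1)

    out = pd.DataFrame({"subject_id": predictors.index})
    lps = {}
    for outcome in OUTCOMES:
        lp = np.zeros(n)
        for name, weight in effects[outcome]:
            lp += weight * zscored[name].to_numpy()
        lps[outcome] = lp
        out[f"t_{outcome}"] = 50.0 + lp + rng.normal(0.0, spec.noise_sd, n)

    intercepts = spec.logistic_intercept
    if not isinstance(intercepts, Mapping):
        intercepts = {"internalizing": intercepts, "externalizing": intercepts}
    for spectrum in ("internalizing", "externalizing"):
        prob = expit(float(intercepts.get(spectrum, 0.0)) + spec.logistic_slope * lps[spectrum])
        out[f"dx_{spectrum}"] = (rng.random(n) < prob).astype(int)
    out["dx_any"] = np.maximum(out["dx_internalizing"], out["dx_externalizing"])
    if subjects is not None:
        out = out.merge(subjects[["subject_id", "sex", "age"]], on="subject_id")
    return out


def generate_cohort(
    spec: SyntheticSpec, thresholds: scoring.ThresholdTable | None = None
) -> dict[str, pd.DataFrame]:
    """Full simulate-and-score convenience wrapper.

    Returns a dict with ``subjects``, ``exposures`` (long), ``predictors``
    (69-column matrix) and ``outcomes``.
    """
    subjects, exposures = generate_exposures(spec)
    predictors = scoring.build_predictor_matrix(exposures, subjects, thresholds)
    outcomes = generate_outcomes(exposures, spec, subjects, predictors)
    return {
        "subjects": subjects,
        "exposures": exposures,
        "predictors": predictors,
        "outcomes": outcomes,
    }
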