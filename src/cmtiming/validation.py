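"""Diagnosis-level validation and descriptive statistics.

Selected predictors from the importance analysis are validated against
interview-based mental-disorder status: ICD-10 F-codes are grouped into
the HiTOP internalizing and externalizing spectra, and each selected
predictor enters its own binomial (logistic) GLM for disorder status
with sex and age as covariates, reported as beta, SE, odds ratio and
Wald p.  Descriptive comparisons between diagnostic groups use Welch's
t-test and Cohen's d from pooled SDs.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "HitopMap",
    "GlmFit",
    "map_diagnoses",
    "map_diagnoses_cohort",
    "fit_disorder_glm",
    "welch_cohen",
    "pearson_matrix",
    "describe_groups",
]

# HiTOP grouping of current ICD-10 F-diagnoses into the two spectra.
# Note the deliberate quirks of the published grouping, kept as printed:
# the internalizing list states both "F41" and the range "F40-F42" (the
# union is harmless), and the externalizing range F10-F25 sweeps in the
# psychotic-disorder codes F20-F25.  Sub-code patterns win over stem
# ranges, so F60.31 (borderline, impulsive type) is internalizing even
# though F60.3 is externalizing.
INTERNALIZING_PATTERNS: tuple[str, ...] = (
    "F32-F34", "F38-F38", "F41", "F43", "F40-F42",
    "F50.1", "F50.3", "F51", "F60.31", "F93.3", "F93.8", "F93",
)
EXTERNALIZING_PATTERNS: tuple[str, ...] = (
    "F10-F25", "F60.2", "F60.3", "F60.4", "F60.81", "F60.0", "F63.2",
    "F90-F92", "F94",
)

_CODE_RE = re.compile(r"^F(\d{1,2})(?:\.(\d+))?$")
_RANGE_RE = re.compile(r"^F(\d{1,2})-F(\d{1,2})$")


def _expand_patterns(patterns: Iterable[str], spectrum: str) -> list[tuple[str, int, str]]:
    """Expand stems/ranges/sub-codes to (normalised prefix, specificity, spectrum)."""
    out = []
    for pat in patterns:
        pat = pat.strip().upper()
        m = _RANGE_RE.match(pat)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            if lo > hi:
                raise ValueError(f"invalid ICD-10 range: {pat}")
            for stem in range(lo, hi + 1):
                out.append((f"F{stem:02d}", 3, spectrum))
            continue
        if not _CODE_RE.match(pat):
            raise ValueError(f"unparseable ICD-10 pattern: {pat}")
        norm = pat.replace(".", "")
        if len(norm) == 2:  # single-digit stem, e.g. F9 -> F09
            norm = f"F0{norm[1:]}"
        out.append((norm, len(norm), spectrum))
    return out


@dataclasses.dataclass(frozen=True)
class HitopMap:
    """Deterministic ICD-10 F-code -> HiTOP spectrum classifier."""

    internalizing_patterns: tuple[str, ...] = INTERNALIZING_PATTERNS
    externalizing_patterns: tuple[str, ...] = EXTERNALIZING_PATTERNS

    def __post_init__(self) -> None:
        rules = _expand_patterns(self.internalizing_patterns, "internalizing")
        rules += _expand_patterns(self.externalizing_patterns, "externalizing")
        object.__setattr__(self, "_rules", tuple(rules))

    def classify(self, code: str) -> str | None:
        """Spectrum of one code ('internalizing'/'externalizing'/None).

        The most specific matching pattern wins; codes matching no
        pattern map to neither spectrum.  Unparseable codes raise.
        """
        norm = str(code).strip().upper().replace(".", "")
        m = _CODE_RE.match(str(code).strip().upper())
        if not m:
            raise ValueError(f"unparseable ICD-10 code: {code!r}")
        if len(m.group(1)) == 1:
            norm = f"F0{norm[1:]}"
        best: tuple[int, str] | None = None
        for prefix, spec, spectrum in self._rules:
            if norm.startswith(prefix) and (best is None or spec > best[0]):
                best = (spec, spectrum)
        return best[1] if best else None


def map_diagnoses(
    codes: Sequence[str], hitop: HitopMap | None = None
) -> tuple[int, int, int]:
    """(dx_any, dx_internalizing, dx_externalizing) for one subject.

    ``dx_any`` is 1 iff at least one code falls in either spectrum.
    Unparseable codes are excluded with a warning rather than failing
    the subject.
    """
    hitop = hitop or HitopMap()
    dx_int = dx_ext = 0
    for code in codes:
        try:
            spectrum = hitop.classify(code)
        except ValueError:
            warnings.warn(f"excluding unparseable ICD-10 code {code!r}", stacklevel=2)
            continue
        if spectrum == "internalizing":
            dx_int = 1
        elif spectrum == "externalizing":
            dx_ext = 1
    return (1 if (dx_int or dx_ext) else 0, dx_int, dx_ext)


def map_diagnoses_cohort(
    diagnoses: pd.DataFrame, hitop: HitopMap | None = None
) -> pd.DataFrame:
    """Vectorised :func:`map_diagnoses` over a long (subject_id, code) table."""
    hitop = hitop or HitopMap()
    rows = {
        sid: map_diagnoses(group["code"].tolist(), hitop)
        for sid, group in diagnoses.groupby("subject_id")
    }
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["dx_any", "dx_internalizing", "dx_externalizing"]
    )
    out.index.name = "subject_id"
    return out


@dataclasses.dataclass(frozen=True)
class GlmFit:
    """One predictor's logistic-regression validation result."""

    predictor: str
    outcome: str
    beta: float
    se: float
    or_: float
    p: float
    n: int
    covariates: tuple[str, ...] = ("sex", "age")
    standardized: bool = True
    warning: str | None = None


def fit_disorder_glm(
    data: pd.DataFrame,
    predictor: str,
    outcome: str,
    covariates: Sequence[str] = ("sex", "age"),
    standardize: bool = True,
) -> GlmFit:
    """Binomial GLM of a binary diagnosis on one predictor plus covariates.

    The predictor is z-scored by default so the odds ratio is per SD,
    comparable across predictors on different scales; ``standardize=False``
    reports the raw-scale coefficient.  Quasi-complete separation does
    not raise — the fit is returned with a warning recorded.
    """
    cols = [predictor, *covariates, outcome]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    frame = data[cols].dropna()
    y = frame[outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError(f"degenerate outcome {outcome!r}: only one class present")
    X = frame[[predictor, *covariates]].astype(float)
    if standardize:
        sd = X[predictor].std(ddof=0)
        if sd == 0:
            raise ValueError(f"predictor {predictor!r} is constant")
        X[predictor] = (X[predictor] - X[predictor].mean()) / sd
    X = sm.add_constant(X, has_constant="add")
    note = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        for w in caught:
            if issubclass(w.category, (PerfectSeparationWarning, RuntimeWarning)):
                note = f"{w.category.__name__}: {w.message}"
    beta = float(result.params[predictor])
    return GlmFit(
        predictor=predictor,
        outcome=outcome,
        beta=beta,
        se=float(result.bse[predictor]),
        or_=float(np.exp(beta)),
        p=float(result.pvalues[predictor]),
        n=len(frame),
        covariates=tuple(covariates),
        standardized=standardize,
        warning=note,
    )


def welch_cohen(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's t, Satterthwaite df, and Cohen's d from group summaries.

    Cohen's d uses the pooled SD
    ``sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2))``; the t-test
    does not assume equal variances.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    d = (mean1 - mean2) / pooled
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(d)


def pearson_matrix(*frames: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix across the given column blocks.

    Zero-variance columns yield masked (NaN) entries; everything else is
    a symmetric matrix with unit diagonal and entries in [-1, 1].
    """
    data = pd.concat([pd.DataFrame(f) for f in frames], axis=1)
    if len(data) < 3:
        raise ValueError("need at least 3 subjects for correlations")
    if not np.isfinite(data.to_numpy(dtype=float)).all():
        raise ValueError("non-finite values in correlation input")
    return data.corr(method="pearson")


def describe_groups(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Welch t / Cohen's d contrasts of T-scores between diagnostic groups.

    For each spectrum, subjects without the diagnosis (group 1) are
    compared with subjects carrying it (group 2) on the matching
    self-report scale, mirroring the conventional descriptive table.
    """
    pairs = [
        ("t_total", "dx_any"),
        ("t_internalizing", "dx_internalizing"),
        ("t_externalizing", "dx_externalizing"),
    ]
    rows = []
    for t_col, dx_col in pairs:
        g0 = outcomes.loc[outcomes[dx_col] == 0, t_col]
        g1 = outcomes.loc[outcomes[dx_col] == 1, t_col]
        if len(g0) < 2 or len(g1) < 2 or g0.std() == 0 or g1.std() == 0:
            continue
        t, df, d = welch_cohen(
            g0.mean(), g0.std(ddof=1), len(g0), g1.mean(), g1.std(ddof=1), len(g1)
        )
        rows.append(
            {
                "t_score": t_col, "diagnosis": dx_col,
                "mean_without": g0.mean(), "sd_without": g0.std(ddof=1), "n_without": len(g0),
                "mean_with": g1.mean(), "sd_with": g1.std(ddof=1), "n_with": len(g1),
                "t": t, "df": df, "cohen_d": d,
                "p": float(2 * stats.t.sf(abs(t), df)),
            }
        )
    return pd.DataFrame(rows)
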