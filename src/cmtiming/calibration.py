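"""Significance of variable importance via a reshuffled-outcome null.

The sampling distribution of permute-refit importance under "no
association" is obtained empirically: the outcome vector is reshuffled
across subjects and the whole importance procedure is rerun, many times
(study scale: 5,000 reshuffles), yielding a chance mean and SD per
predictor.  A one-sided Z-test then gives the probability of observing
an importance at least as high by chance.

Cost control and calibration.  The observed importance is a mean over
``k = n_split_reps`` train/test splits, so its null sampling variance
is ``v_b + v_w / k`` — a between-reshuffle component plus a within-
outcome procedure-noise component.  Empirically the procedure noise
``v_w`` dominates by an order of magnitude at cohort sizes of a few
hundred, so a null built from *single-split* replicates (variance
``v_b + v_w``) badly overstates the reference SD and makes the Z-test
severely conservative; no stable moment correction exists because it
would subtract two nearly equal noisy variances.  Each null replicate
therefore repeats the full k-split averaging by default, making the
null draws exchangeable with the observed statistic under H0.  With a
modest number R of such replicates, :func:`attach_significance` uses
the exact finite-R reference: ``(vi_mean - null_mean) / (null_sd *
sqrt(1 + 1/R))`` against Student-t with R - 1 degrees of freedom,
which converges to the plain Z-test as R grows (at the study's scale of
thousands of reshuffles the two are indistinguishable).  Shallower
nulls (``null_split_reps < n_split_reps``) remain available and are
scored with the plain Z-test, but their p-values are conservative.

This module also hosts the competitive comparison between global
maltreatment burden (SEVERITY, MULTI, DURATION) and the type-by-age
predictors, and the selection of the strongest significant predictor
per maltreatment type for diagnosis-level validation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np
import pandas as pd
from scipy import stats

from .forest import ForestConfig, _ROLE_NULL, _rng, estimate_vi
from .subscales import GLOBAL_INDICES, parse_type_age

__all__ = [
    "NullDistribution",
    "config_hash",
    "build_null",
    "z_test",
    "attach_significance",
    "competitive_compare",
    "select_top_per_type",
]

# Split-repetition indices used by null replicates start here, so the
# null never reuses the observed analysis' split/forest/permutation
# streams while sharing every configuration field.
_NULL_REP_OFFSET = 1 << 20


def config_hash(config: ForestConfig, exclude: tuple[str, ...] = ("n_split_reps",)) -> str:
    """Stable hash of the engine settings shared by observed and null runs."""
    d = {k: v for k, v in dataclasses.asdict(config).items() if k not in exclude}
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


@dataclasses.dataclass(frozen=True)
class NullDistribution:
    """Per-predictor chance importance moments from outcome reshuffling."""

    null_mean: pd.Series
    null_sd: pd.Series
    n_null_reps: int
    null_split_reps: int
    config_digest: str
    per_rep: pd.DataFrame | None = None


def build_null(
    X: pd.DataFrame,
    y,
    config: ForestConfig,
    n_null_reps: int = 40,
    null_split_reps: int | None = None,
    keep_reps: bool = True,
) -> NullDistribution:
    """Empirical null importance distribution via outcome reshuffling.

    Each replicate permutes ``y`` across subjects (its own seeded
    stream) and reruns the importance procedure on the identical
    predictor matrix and engine settings, averaging ``null_split_reps``
    train/test splits — by default ``config.n_split_reps``, the same
    depth as the observed analysis, so null replicates are exchangeable
    with the observed statistic under H0.  Moments are taken over
    replicates with ``ddof=1``.
    """
    if n_null_reps < 2:
        raise ValueError("n_null_reps must be >= 2")
    if null_split_reps is None:
        null_split_reps = config.n_split_reps
    y = np.asarray(y, dtype=float)
    rows = []
    for r in range(n_null_reps):
        y_null = y[_rng(config, _ROLE_NULL, r).permutation(len(y))]
        reps = [_NULL_REP_OFFSET + r * null_split_reps + s for s in range(null_split_reps)]
        summary, _ = estimate_vi(X, y_null, config, rep_indices=reps)
        rows.append(summary["vi_mean"])
    per_rep = pd.DataFrame(rows, index=range(n_null_reps))
    return NullDistribution(
        null_mean=per_rep.mean(axis=0),
        null_sd=per_rep.std(axis=0, ddof=1),
        n_null_reps=n_null_reps,
        null_split_reps=null_split_reps,
        config_digest=config_hash(config),
        per_rep=per_rep if keep_reps else None,
    )


def z_test(vi_mean: float, null_mean: float, null_sd: float) -> tuple[float, float]:
    """One-sided Z-test of an observed importance against the null moments.

    ``z = (vi_mean - null_mean) / null_sd``; ``p`` is the upper-tail
    standard-normal probability of a chance importance at least this
    high.  Raises for a degenerate (zero-SD) null.
    """
    if null_sd <= 0:
        raise ValueError("degenerate null: null_sd must be > 0")
    z = (vi_mean - null_mean) / null_sd
    return float(z), float(stats.norm.sf(z))


def attach_significance(
    summary: pd.DataFrame,
    null: NullDistribution,
    per_rep: pd.DataFrame | None = None,
    alpha: float = 0.05,
    config: ForestConfig | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Assemble the full VI table: importance, null moments, z, p, flags.

    If ``config`` is given, its hash is checked against the one recorded
    by :func:`build_null`, asserting that observed and null pipelines
    shared every setting except the outcome reshuffle.

    When the null replicates average the same number of splits as the
    observed analysis (the default), p-values come from the exact
    finite-R Student-t reference described in the module docstring;
    with a structurally shallower null the plain normal upper tail is
    used (conservative).  Predictors with a degenerate null SD are
    flagged and excluded from significance calls.  ``per_rep`` (the
    observed repetitions x predictors dMSE matrix) is accepted for
    interface symmetry and structural checks only.

    ``fdr=True`` additionally applies a Benjamini-Hochberg correction
    (off by default; per-predictor raw p-values are the primary output).
    """
    if config is not None and config_hash(config) != null.config_digest:
        raise ValueError(
            "null distribution was built under different engine settings "
            "than the observed analysis"
        )
    table = summary.copy()
    table["null_mean"] = null.null_mean.reindex(table.index)
    table["null_sd"] = null.null_sd.reindex(table.index)
    degenerate = ~(table["null_sd"] > 0)

    k = len(per_rep) if per_rep is not None else None
    matched = k is None or null.null_split_reps == k
    R = null.n_null_reps

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (table["vi_mean"] - table["null_mean"]) / table["null_sd"]
        if matched:
            p = pd.Series(
                stats.t.sf(z / np.sqrt(1.0 + 1.0 / R), df=R - 1), index=table.index
            )
        else:
            p = pd.Series(stats.norm.sf(z), index=table.index)
    table["z"] = z.where(~degenerate)
    table["p"] = p.where(~degenerate)
    table["degenerate"] = degenerate
    if fdr:
        ok = table["p"].notna()
        adj = table["p"].copy()
        adj[ok] = stats.false_discovery_control(table.loc[ok, "p"], method="bh")
        table["p_adjusted"] = adj
        table["significant"] = (adj < alpha).fillna(False) & ~degenerate
    else:
        table["significant"] = (table["p"] < alpha).fillna(False) & ~degenerate
    return table


def _split_groups(table: pd.DataFrame) -> tuple[list, list]:
    global_rows = [p for p in table.index if p in GLOBAL_INDICES]
    specific_rows = [p for p in table.index if parse_type_age(p) is not None]
    return global_rows, specific_rows


def competitive_compare(
    table: pd.DataFrame,
    global_predictors: list | None = None,
    specific_predictors: list | None = None,
) -> dict:
    """Compare global burden against the best type-by-age predictor.

    Returns the strongest member of each group (by ``vi_mean``), their
    overall ranks within the union of the two groups, and the verdict:
    ``"global"`` when a global index out-predicts every type-by-age
    cell, ``"specific"`` for the converse, ``"tie"`` on an exact tie
    (broken lexicographically and flagged).
    """
    if global_predictors is None or specific_predictors is None:
        g, s = _split_groups(table)
        global_predictors = global_predictors or g
        specific_predictors = specific_predictors or s
    if not global_predictors or not specific_predictors:
        raise ValueError("both predictor groups must be nonempty")

    def best(names):
        sub = table.loc[names, "vi_mean"]
        top = sub.max()
        winners = sorted(sub.index[sub == top])
        return winners[0], float(top)

    best_global, vi_global = best(global_predictors)
    best_specific, vi_specific = best(specific_predictors)
    pool = table.loc[list(global_predictors) + list(specific_predictors), "vi_mean"]
    ranks = pool.rank(ascending=False, method="min")
    tie = vi_global == vi_specific
    verdict = "tie" if tie else ("global" if vi_global > vi_specific else "specific")
    winner = min(best_global, best_specific) if tie else (
        best_global if verdict == "global" else best_specific
    )
    return {
        "verdict": verdict,
        "winner": winner,
        "tie": tie,
        "best_global": best_global,
        "best_global_vi": vi_global,
        "best_global_rank": int(ranks[best_global]),
        "best_specific": best_specific,
        "best_specific_vi": vi_specific,
        "best_specific_rank": int(ranks[best_specific]),
    }


def select_top_per_type(table: pd.DataFrame, alpha: float | None = None) -> dict[str, str]:
    """Strongest *significant* type-by-age predictor per maltreatment type.

    Types with no significant cell are omitted.  Uses the table's
    ``significant`` flag unless an explicit ``alpha`` is given.
    """
    selected: dict[str, str] = {}
    for name in table.index:
        parsed = parse_type_age(name)
        if parsed is None:
            continue
        cm_type, _age = parsed
        if alpha is not None:
            ok = pd.notna(table.loc[name, "p"]) and table.loc[name, "p"] < alpha
        else:
            ok = bool(table.loc[name, "significant"])
        if not ok:
            continue
        cur = selected.get(cm_type)
        if cur is None or table.loc[name, "vi_mean"] > table.loc[cur, "vi_mean"] or (
            table.loc[name, "vi_mean"] == table.loc[cur, "vi_mean"] and name < cur
        ):
            selected[cm_type] = name
    return selected
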