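"""Chronology scoring: type aggregation, global indices, prevalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmtiming.scoring import (
    ThresholdTable,
    aggregate_to_types,
    build_predictor_matrix,
    compute_duration,
    compute_multiplicity,
    compute_severity,
    exclude_infantile_years,
    long_to_wide,
    prevalence_by_age,
)
from cmtiming.subscales import AGES_PREDICTOR, CM_TYPES, SUBSCALES, TYPE_MAP

from conftest import make_wide

ABUSE_SUBS = TYPE_MAP["ABUSE"]


class TestAggregateToTypes:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ((0, 0, 0, 0, 0), 0.0),  # no exposure in any constituent subscale
            ((10, 10, 10, 10, 10), 10.0),  # ceiling preserved by the mean
            ((10, 5, 0, 0, 0), 3.0),  # arithmetic of the mean rule
        ],
    )
    def test_mean_rule_on_abuse_age7(self, values, expected):
        wide = make_wide({(sub, 7): v for sub, v in zip(ABUSE_SUBS, values)})
        types = aggregate_to_types(wide)
        assert types.loc["s1", ("ABUSE", 7)] == pytest.approx(expected)

    def test_max_rule(self):
        wide = make_wide({(ABUSE_SUBS[0], 7): 10, (ABUSE_SUBS[1], 7): 5})
        types = aggregate_to_types(wide, rule="max")
        assert types.loc["s1", ("ABUSE", 7)] == 10.0

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="rule"):
            aggregate_to_types(make_wide({}), rule="median")

    def test_scores_stay_on_common_scale(self, small_cohort):
        types = aggregate_to_types(long_to_wide(small_cohort["exposures"]))
        vals = types.to_numpy()
        assert vals.min() >= 0 and vals.max() <= 10


class TestInfantileExclusion:
    def test_drops_to_16_ages_and_64_type_columns(self):
        types = aggregate_to_types(make_wide({("sexual_abuse", 1): 3}))
        restricted = exclude_infantile_years(types)
        assert sorted(set(restricted.columns.get_level_values("age"))) == list(range(3, 19))
        assert restricted.shape[1] == 4 * 16 == 64

    def test_idempotent(self):
        types = aggregate_to_types(make_wide({("sexual_abuse", 5): 3}))
        once = exclude_infantile_years(types)
        pd.testing.assert_frame_equal(once, exclude_infantile_years(once))

    def test_only_predictors_lose_infancy_global_indices_keep_it(self):
        # Exposure only at age 1: invisible to type-age predictors, still
        # counted by the global indices under the default 1-18 window.
        long = make_wide({("sexual_abuse", 1): 8.0}).pipe(
            lambda w: w.stack(["subscale", "age"], future_stack=True)
            .rename("score")
            .reset_index()
        )
        long.columns = ["subject_id", "subscale", "age", "score"]
        matrix = build_predictor_matrix(long)
        assert matrix.loc["s1", [f"SEXA_{a:02d}" for a in AGES_PREDICTOR]].sum() == 0
        assert matrix.loc["s1", "SEVERITY"] == 8.0
        assert matrix.loc["s1", "DURATION"] == 1
        restricted = build_predictor_matrix(long, global_age_window=(3, 18))
        assert restricted.loc["s1", "SEVERITY"] == 0.0


class TestGlobalIndices:
    def test_zero_chronology_scores_zero(self):
        wide = make_wide({})
        thresholds = ThresholdTable()
        assert compute_severity(wide).iloc[0] == 0
        assert compute_multiplicity(wide, thresholds).iloc[0] == 0
        assert compute_duration(wide, thresholds).iloc[0] == 0

    def test_maximal_chronology_hits_printed_ranges(self):
        wide = make_wide({(s, a): 10.0 for s in SUBSCALES for a in range(1, 19)})
        thresholds = ThresholdTable()
        assert compute_severity(wide).iloc[0] == 100.0
        assert compute_multiplicity(wide, thresholds).iloc[0] == 10
        assert compute_duration(wide, thresholds).iloc[0] == 18

    def test_severity_sums_subscale_peaks(self):
        wide = make_wide(
            {(SUBSCALES[0], 4): 5.0, (SUBSCALES[0], 9): 2.0, (SUBSCALES[1], 12): 5.0}
        )
        assert compute_severity(wide).iloc[0] == 10.0

    def test_multiplicity_counts_subscales_above_threshold(self):
        wide = make_wide(
            {(SUBSCALES[0], 4): 3.0, (SUBSCALES[3], 6): 1.0, (SUBSCALES[9], 2): 0.6,
             (SUBSCALES[5], 8): 0.4}  # below the 0.5 default threshold
        )
        assert compute_multiplicity(wide, ThresholdTable()).iloc[0] == 3

    def test_duration_counts_years_not_subscales(self):
        wide = make_wide(
            {(SUBSCALES[0], 4): 3.0, (SUBSCALES[1], 4): 2.0, (SUBSCALES[0], 5): 1.0,
             (SUBSCALES[9], 9): 2.0}
        )
        assert compute_duration(wide, ThresholdTable()).iloc[0] == 3

    def test_one_subscale_every_year_gives_18(self):
        wide = make_wide({("physical_neglect", a): 2.0 for a in range(1, 19)})
        assert compute_duration(wide, ThresholdTable()).iloc[0] == 18


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    cells=st.lists(
        st.tuples(
            st.sampled_from(SUBSCALES),
            st.integers(1, 18),
            st.floats(0, 10, allow_nan=False),
        ),
        max_size=12,
    ),
    extra=st.tuples(
        st.sampled_from(SUBSCALES), st.integers(1, 18), st.floats(0.01, 10)
    ),
)
def test_global_indices_monotone_under_added_exposure(cells, extra):
    """Adding exposure never decreases SEVERITY, MULTI or DURATION."""
    base = {}
    for sub, age, score in cells:
        base[(sub, age)] = max(base.get((sub, age), 0.0), score)
    sub, age, score = extra
    augmented = dict(base)
    augmented[(sub, age)] = min(10.0, base.get((sub, age), 0.0) + score)
    w0, w1 = make_wide(base), make_wide(augmented)
    thresholds = ThresholdTable()
    assert compute_severity(w1).iloc[0] >= compute_severity(w0).iloc[0] - 1e-12
    assert compute_multiplicity(w1, thresholds).iloc[0] >= compute_multiplicity(w0, thresholds).iloc[0]
    assert compute_duration(w1, thresholds).iloc[0] >= compute_duration(w0, thresholds).iloc[0]


class TestPrevalence:
    def test_all_zero_cohort(self):
        wide = make_wide({}, subjects=[f"s{i}" for i in range(5)])
        assert (prevalence_by_age(wide).to_numpy() == 0).all()

    def test_all_exposed_cohort(self):
        wide = make_wide(
            {(s, a): 5.0 for s in SUBSCALES for a in range(1, 19)},
            subjects=[f"s{i}" for i in range(5)],
        )
        assert (prevalence_by_age(wide).to_numpy() == 1).all()

    def test_counting(self):
        rows = []
        for i in range(10):
            score = 5.0 if i < 9 else 0.0
            rows.append({"subject_id": f"s{i}", "subscale": "physical_neglect",
                         "age": 6, "score": score})
        prev = prevalence_by_age(pd.DataFrame(rows))
        assert prev.loc["NEGLECT", 6] == pytest.approx(0.9)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            prevalence_by_age(make_wide({}).iloc[:0])

    def test_any_cm_prevalence_matches_brute_force(self, small_cohort):
        """MULTI > 0 is exactly the per-subject union of above-threshold subscales."""
        thresholds = ThresholdTable()
        exposures = small_cohort["exposures"]
        brute = (
            exposures.assign(
                above=lambda d: d["score"]
                > thresholds.values.reindex(d["subscale"]).to_numpy()
            )
            .groupby("subject_id")["above"]
            .any()
        )
        via_multi = small_cohort["predictors"]["MULTI"] > 0
        assert brute.sort_index().equals(via_multi.sort_index())


class TestPredictorMatrix:
    def test_column_accounting(self, small_cohort):
        matrix = small_cohort["predictors"]
        assert matrix.shape[1] == 64 + 3 + 2
        assert list(matrix.columns[:1]) == ["ABUSE_03"]
        assert list(matrix.columns[-5:]) == ["SEVERITY", "MULTI", "DURATION", "sex", "age"]

    def test_ranges_and_integrality(self, small_cohort):
        matrix = small_cohort["predictors"]
        type_age = matrix.iloc[:, :64]
        assert type_age.to_numpy().min() >= 0 and type_age.to_numpy().max() <= 10
        assert matrix["SEVERITY"].between(0, 100).all()
        assert matrix["MULTI"].between(0, 10).all()
        assert matrix["DURATION"].between(0, 18).all()
        assert (matrix["MULTI"] == matrix["MULTI"].astype(int)).all()
        assert (matrix["DURATION"] == matrix["DURATION"].astype(int)).all()

    def test_unknown_subscale_label_rejected(self):
        bad = pd.DataFrame(
            [{"subject_id": "s1", "subscale": "not_a_subscale", "age": 5, "score": 1.0}]
        )
        with pytest.raises(ValueError, match="unknown subscale"):
            long_to_wide(bad)


class TestThresholdTable:
    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 10\]"):
            ThresholdTable.uniform(11.0)

    def test_missing_subscale_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ThresholdTable.from_mapping({"sexual_abuse": 1.0})

    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        path = tmp_path / "thr.yaml"
        path.write_text(yaml.safe_dump({s: 1.5 for s in SUBSCALES}))
        table = ThresholdTable.from_yaml(path)
        assert (table.values == 1.5).all()
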