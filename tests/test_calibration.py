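"""Reshuffled-outcome null, Z-tests, competitive comparison, selection."""

import numpy as np
import pandas as pd
import pytest

from cmtiming.calibration import (
    attach_significance,
    build_null,
    competitive_compare,
    config_hash,
    select_top_per_type,
    z_test,
)
from cmtiming.forest import ForestConfig, estimate_vi


def vi_table(entries: dict[str, float], sig: dict[str, bool] | None = None) -> pd.DataFrame:
    table = pd.DataFrame({"vi_mean": pd.Series(entries)})
    table["p"] = 0.5
    table["significant"] = pd.Series(sig or {}, dtype=bool).reindex(table.index, fill_value=False)
    return table


class TestZTest:
    def test_chance_level_importance(self):
        z, p = z_test(1.0, 1.0, 0.5)
        assert z == 0.0 and p == 0.5

    def test_three_sigma_upper_tail(self):
        _, p = z_test(2.5, 1.0, 0.5)
        assert p == pytest.approx(0.00135, rel=1e-2)

    def test_below_chance_never_significant(self):
        _, p = z_test(0.5, 1.0, 0.5)
        assert p > 0.5

    def test_p_strictly_decreasing_in_vi(self):
        ps = [z_test(v, 0.0, 1.0)[1] for v in np.linspace(-2, 4, 13)]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            z_test(1.0, 0.0, 0.0)


@pytest.fixture(scope="module")
def tiny_null_setup():
    rng = np.random.default_rng(31)
    X = pd.DataFrame(rng.normal(size=(80, 3)), columns=["a", "b", "c"])
    y = rng.normal(size=80)
    cfg = ForestConfig(n_trees=8, max_depth=4, n_split_reps=4, seed=31)
    return X, y, cfg


class TestBuildNull:
    def test_requires_two_reps(self, tiny_null_setup):
        X, y, cfg = tiny_null_setup
        with pytest.raises(ValueError, match="n_null_reps"):
            build_null(X, y, cfg, n_null_reps=1)

    def test_deterministic(self, tiny_null_setup):
        X, y, cfg = tiny_null_setup
        a = build_null(X, y, cfg, n_null_reps=10)
        b = build_null(X, y, cfg, n_null_reps=10)
        pd.testing.assert_series_equal(a.null_mean, b.null_mean)
        pd.testing.assert_series_equal(a.null_sd, b.null_sd)

    def test_null_sd_positive_for_nonconstant_predictors(self, tiny_null_setup):
        X, y, cfg = tiny_null_setup
        null = build_null(X, y, cfg, n_null_reps=100)
        assert (null.null_sd > 0).all()

    def test_config_mismatch_detected(self, tiny_null_setup):
        X, y, cfg = tiny_null_setup
        summary, per_rep = estimate_vi(X, y, cfg)
        null = build_null(X, y, cfg, n_null_reps=10)
        other = ForestConfig(n_trees=9, max_depth=4, n_split_reps=4, seed=31)
        assert config_hash(cfg) != config_hash(other)
        with pytest.raises(ValueError, match="different engine settings"):
            attach_significance(summary, null, per_rep=per_rep, config=other)

    def test_null_split_reps_differ_only_in_depth(self, tiny_null_setup):
        """Matching the observed split depth recovers the plain Z-test."""
        X, y, cfg = tiny_null_setup
        summary, per_rep = estimate_vi(X, y, cfg)
        null = build_null(X, y, cfg, n_null_reps=12, null_split_reps=cfg.n_split_reps)
        table = attach_significance(summary, null, per_rep=per_rep, config=cfg)
        z_expected = (table["vi_mean"] - table["null_mean"]) / table["null_sd"]
        assert np.allclose(table["z"], z_expected)


class TestScalingInvariance:
    def test_outcome_scaling_leaves_z_and_p_invariant(self, tiny_null_setup):
        """y -> 10y scales all dMSE moments by 100 but not z or p."""
        X, y, cfg = tiny_null_setup
        tables = {}
        for scale in (1.0, 10.0):
            summary, per_rep = estimate_vi(X, scale * y, cfg)
            null = build_null(X, scale * y, cfg, n_null_reps=15)
            tables[scale] = attach_significance(summary, null, per_rep=per_rep)
        ratio = tables[10.0]["vi_mean"] / tables[1.0]["vi_mean"]
        assert np.allclose(ratio, 100.0, rtol=1e-6)
        assert np.allclose(tables[10.0]["null_sd"] / tables[1.0]["null_sd"], 100.0, rtol=1e-6)
        assert np.allclose(tables[10.0]["z"], tables[1.0]["z"], rtol=1e-6)
        assert np.allclose(tables[10.0]["p"], tables[1.0]["p"], rtol=1e-6)


class TestAttachSignificance:
    def test_degenerate_predictor_flagged_not_significant(self, tiny_null_setup):
        X, y, cfg = tiny_null_setup
        X = X.copy()
        X["const"] = 1.0
        summary, per_rep = estimate_vi(X, y, cfg)
        null = build_null(X, y, cfg, n_null_reps=10)
        table = attach_significance(summary, null, per_rep=per_rep)
        assert bool(table.loc["const", "degenerate"])
        assert not bool(table.loc["const", "significant"])
        assert np.isnan(table.loc["const", "p"])

    def test_fdr_option_is_more_conservative(self, tiny_null_setup):
        X, y, cfg = tiny_null_setup
        summary, per_rep = estimate_vi(X, y, cfg)
        null = build_null(X, y, cfg, n_null_reps=20)
        raw = attach_significance(summary, null, per_rep=per_rep)
        adj = attach_significance(summary, null, per_rep=per_rep, fdr=True)
        assert (adj["p_adjusted"] >= raw["p"] - 1e-12).all()


class TestCompetitiveCompare:
    def test_global_dominates(self):
        table = vi_table(
            {"SEVERITY": 3.02, "MULTI": 2.07, "DURATION": 1.78, "PEER_14": 1.2,
             "ABUSE_06": 0.78}
        )
        comp = competitive_compare(table)
        assert comp["verdict"] == "global"
        assert comp["winner"] == "SEVERITY"
        assert comp["best_specific"] == "PEER_14"
        assert comp["best_global_rank"] == 1

    def test_specific_dominates(self):
        table = vi_table(
            {"SEVERITY": 2.22, "MULTI": 0.84, "DURATION": 0.1, "ABUSE_03": 3.57,
             "PEER_17": 1.55}
        )
        comp = competitive_compare(table)
        assert comp["verdict"] == "specific"
        assert comp["winner"] == "ABUSE_03"
        assert comp["best_specific_rank"] == 1

    def test_tie_flagged_with_lexicographic_winner(self):
        table = vi_table({"SEVERITY": 2.0, "ABUSE_03": 2.0})
        comp = competitive_compare(table)
        assert comp["verdict"] == "tie" and comp["tie"]
        assert comp["winner"] == "ABUSE_03"  # lexicographic tiebreak

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            competitive_compare(vi_table({"SEVERITY": 1.0}))


class TestSelectTopPerType:
    def test_strongest_significant_cell_per_type(self):
        entries = {"ABUSE_03": 1.2, "ABUSE_05": 0.9, "ABUSE_06": 1.63, "ABUSE_07": 1.0,
                   "NEGLECT_08": 2.0, "PEER_14": 1.21, "SEVERITY": 2.72}
        sig = {k: True for k in entries}
        sig["NEGLECT_08"] = False  # no significant neglect cell
        selected = select_top_per_type(vi_table(entries, sig))
        assert selected == {"ABUSE": "ABUSE_06", "PEER": "PEER_14"}

    def test_single_significant_cell(self):
        selected = select_top_per_type(
            vi_table({"SEXA_18": 0.06, "SEXA_17": 0.9}, {"SEXA_18": True})
        )
        assert selected == {"SEXA": "SEXA_18"}

    def test_alpha_override_uses_p_column(self):
        table = vi_table({"ABUSE_06": 1.0, "ABUSE_03": 0.5})
        table.loc["ABUSE_06", "p"] = 0.01
        table.loc["ABUSE_03", "p"] = 0.2
        assert select_top_per_type(table, alpha=0.05) == {"ABUSE": "ABUSE_06"}
        assert select_top_per_type(table, alpha=0.3) == {"ABUSE": "ABUSE_06"}
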