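import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fiberdens import (
    BehaviorSimParams,
    analyze_design,
    build_contrast_set,
    generate_behavior_table,
    linear_trend_weights,
    simple_effects,
)
from fiberdens import test_contrast as run_contrast  # avoid pytest collection

B2 = {"treatment": ("CTL", "SAP")}
B4 = {"group": ("Pre", "Post"), "treatment": ("CTL", "SAP")}
W = {"devaluation": ("Ndev", "Dev")}


class TestBuildContrastSet:
    def test_one_between_one_within_gives_three(self):
        specs = build_contrast_set(B2, W)
        assert [s.name for s in specs] == [
            "treatment", "devaluation", "treatment x devaluation"]

    def test_two_between_one_within_gives_seven(self):
        specs = build_contrast_set(B4, W)
        assert len(specs) == 7  # 2^3 - 1

    def test_all_pairs_orthogonal(self):
        specs = build_contrast_set(B4, W)
        for a, b in itertools.combinations(specs, 2):
            assert abs(a.cell_weight_vector() @ b.cell_weight_vector()) < 1e-12

    def test_multilevel_factor_out_of_scope(self):
        with pytest.raises(NotImplementedError):
            build_contrast_set({"region": ("VO", "LO", "MO")}, W)

    def test_linear_trend_weights_centered(self):
        w = linear_trend_weights([1, 2, 3, 4])
        assert list(w.values()) == [-1.5, -0.5, 0.5, 1.5]
        assert sum(w.values()) == 0


class TestTestContrast:
    def test_constant_data_gives_zero_f(self):
        t = generate_behavior_table(BehaviorSimParams(
            n_per_cell=4, between_factors=B2, subject_sd=0, residual_sd=0))
        spec = build_contrast_set(B2, W)[0]
        with pytest.warns(UserWarning, match="zero error variance"):
            res = run_contrast(t, spec)
        assert res.F == 0.0

    def test_between_f_equals_pooled_t_squared(self):
        for seed in range(30):
            t = generate_behavior_table(BehaviorSimParams(
                n_per_cell=6, between_factors=B2, devaluation_effect=2, seed=seed))
            spec = [s for s in build_contrast_set(B2, W) if s.name == "treatment"][0]
            res = run_contrast(t, spec)
            means = t.groupby(["subject", "treatment"])["response"].mean().reset_index()
            a = means.loc[means.treatment == "CTL", "response"]
            b = means.loc[means.treatment == "SAP", "response"]
            tt = stats.ttest_ind(a, b)
            assert res.F == pytest.approx(tt.statistic ** 2, abs=1e-8)
            assert res.p == pytest.approx(tt.pvalue, abs=1e-10)

    def test_between_ss_partition_on_balanced_data(self):
        for seed in range(20):
            t = generate_behavior_table(BehaviorSimParams(
                n_per_cell=5, between_factors=B4, devaluation_effect=1, seed=seed))
            specs = [s for s in build_contrast_set(B4, W)
                     if "devaluation" not in s.name]
            ss = sum(run_contrast(t, s).ss_contrast for s in specs)
            means = t.groupby(["subject", "group", "treatment"])["response"] \
                     .mean().reset_index()
            grand = means["response"].mean()
            cells = means.groupby(["group", "treatment"])["response"] \
                         .agg(["mean", "count"])
            ss_between = float((cells["count"] * (cells["mean"] - grand) ** 2).sum())
            assert ss == pytest.approx(ss_between, abs=1e-8)

    def test_matches_mixed_anova_reference(self):
        pg = pytest.importorskip("pingouin")
        t = generate_behavior_table(BehaviorSimParams(
            n_per_cell=8, between_factors=B2, devaluation_effect=2, seed=3))
        aov = pg.mixed_anova(data=t, dv="response", within="devaluation",
                             subject="subject", between="treatment").set_index("Source")
        by_name = {s.name: run_contrast(t, s) for s in build_contrast_set(B2, W)}
        assert by_name["treatment"].F == pytest.approx(aov.loc["treatment", "F"], rel=1e-9)
        assert by_name["devaluation"].F == pytest.approx(aov.loc["devaluation", "F"], rel=1e-9)
        assert by_name["treatment x devaluation"].F == pytest.approx(
            aov.loc["Interaction", "F"], rel=1e-9)

    def test_affine_response_invariance(self):
        t = generate_behavior_table(BehaviorSimParams(
            n_per_cell=5, between_factors=B4, devaluation_effect=2, seed=9))
        specs = build_contrast_set(B4, W)
        base = [run_contrast(t, s).F for s in specs]
        shifted = t.assign(response=t.response + 100.0)
        scaled = t.assign(response=t.response * 3.5)
        for tab in (shifted, scaled):
            fs = [run_contrast(tab, s).F for s in specs]
            np.testing.assert_allclose(fs, base, rtol=1e-9)

    def test_error_df_is_n_minus_cells(self):
        t = generate_behavior_table(BehaviorSimParams(
            n_per_cell=14, between_factors=B4, seed=0))
        res = run_contrast(t, build_contrast_set(B4, W)[0])
        assert res.df2 == 4 * 14 - 4  # 52, the F(1, N - cells) convention

    def test_unbalanced_cells_supported(self):
        t = generate_behavior_table(BehaviorSimParams(
            n_per_cell=6, between_factors=B2, seed=4))
        # drop one SAP subject -> 6 vs 5
        drop = t[t.treatment == "SAP"]["subject"].iloc[0]
        t = t[t.subject != drop]
        res = run_contrast(t, build_contrast_set(B2, W)[0])
        assert res.df2 == 11 - 2


class TestSimpleEffects:
    def _table(self, delta_ctl, delta_sap, n=4, noise=0.0, seed=0):
        t = generate_behavior_table(BehaviorSimParams(
            n_per_cell=n, between_factors=B2, subject_sd=1.0,
            residual_sd=noise, seed=seed))
        wide = t.pivot_table(index=["subject", "treatment"],
                             columns="devaluation", values="response").reset_index()
        wide.loc[wide.treatment == "CTL", "Dev"] -= delta_ctl
        wide.loc[wide.treatment == "SAP", "Dev"] -= delta_sap
        return wide.melt(id_vars=["subject", "treatment"],
                         value_vars=["Ndev", "Dev"], var_name="devaluation",
                         value_name="response")

    def test_zero_interaction_gives_identical_simple_effects(self):
        # deterministic table: identical devaluation-score distributions
        # {2, 4} in both treatment groups -> symmetric simple effects
        rows = []
        for i, (trt, nd, dv) in enumerate([
            ("CTL", 10, 8), ("CTL", 12, 8), ("SAP", 9, 7), ("SAP", 11, 7),
        ]):
            rows += [
                {"subject": f"s{i}", "treatment": trt, "devaluation": "Ndev",
                 "response": nd},
                {"subject": f"s{i}", "treatment": trt, "devaluation": "Dev",
                 "response": dv},
            ]
        t = pd.DataFrame(rows)
        inter = [s for s in build_contrast_set(B2, W)
                 if s.name == "treatment x devaluation"][0]
        res = simple_effects(t, inter, "treatment")
        assert res[0].F == pytest.approx(res[1].F, rel=1e-12)
        assert res[0].F > 0

    def test_effect_localized_to_one_level(self):
        t = self._table(delta_ctl=4.0, delta_sap=0.0, noise=0.5, seed=3)
        inter = [s for s in build_contrast_set(B2, W)
                 if s.name == "treatment x devaluation"][0]
        res = {r.condition_level: r for r in simple_effects(t, inter, "treatment")}
        assert res["CTL"].F > res["SAP"].F
        assert res["CTL"].significant and not res["SAP"].significant

    def test_pooled_df2_constant_across_levels(self):
        t = self._table(delta_ctl=4.0, delta_sap=1.0, noise=0.5, seed=4)
        inter = [s for s in build_contrast_set(B2, W)
                 if s.name == "treatment x devaluation"][0]
        res = simple_effects(t, inter, "treatment")
        assert res[0].df2 == res[1].df2 == len(t["subject"].unique()) - 2

    def test_self_consistency_with_hand_built_contrast(self):
        # simple effect of devaluation in CTL == mean CTL diff vs pooled error
        t = self._table(delta_ctl=4.0, delta_sap=1.0, noise=0.8, seed=5)
        inter = [s for s in build_contrast_set(B2, W)
                 if s.name == "treatment x devaluation"][0]
        res = {r.condition_level: r for r in simple_effects(t, inter, "treatment")}
        wide = t.pivot_table(index=["subject", "treatment"],
                             columns="devaluation", values="response").reset_index()
        wide["score"] = wide["Ndev"] - wide["Dev"]
        cells = wide.groupby("treatment")["score"]
        sse = sum(((g - g.mean()) ** 2).sum() for _, g in cells)
        df2 = len(wide) - 2
        mse = sse / df2
        for lev in ("CTL", "SAP"):
            g = wide[wide.treatment == lev]["score"]
            f_hand = g.mean() ** 2 / (mse / len(g))
            assert res[lev].F == pytest.approx(f_hand, rel=1e-9)

    def test_condition_on_within_factor(self):
        t = self._table(delta_ctl=4.0, delta_sap=0.0, noise=0.5, seed=6)
        inter = [s for s in build_contrast_set(B2, W)
                 if s.name == "treatment x devaluation"][0]
        res = simple_effects(t, inter, "devaluation")
        assert {r.condition_level for r in res} == {"Ndev", "Dev"}


class TestAnalyzeDesign:
    def test_single_subject_per_cell_rejected(self):
        t = generate_behavior_table(BehaviorSimParams(
            n_per_cell=2, between_factors=B2, seed=0))
        t = t[t.subject.isin(["s001", "s003"])]
        with pytest.raises(ValueError, match="subject"):
            analyze_design(t, B2, W)

    def test_interaction_triggers_simple_effects(self):
        t = generate_behavior_table(BehaviorSimParams(
            n_per_cell=14, between_factors=B2, devaluation_effect=6.0,
            affected_cells=[{"treatment": "CTL"}], seed=1))
        rep = analyze_design(t, B2, W)
        ct = rep["contrast_table"].set_index("contrast")
        assert ct.loc["treatment x devaluation", "significant"]
        assert len(rep["simple_effects"]) == 2

    def test_incomplete_within_data_rejected(self):
        t = generate_behavior_table(BehaviorSimParams(
            n_per_cell=3, between_factors=B2, seed=0))
        with pytest.raises(ValueError, match="complete"):
            analyze_design(t.iloc[:-1], B2, W)
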