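import numpy as np
import pandas as pd
import pytest

from fosnet import (CohortSpec, ValidationError, fishers_lsd, generate_cohort,
                    screen_all_regions, two_way_anova)
from conftest import make_table
from oracles import brute_anova_type3


class TestTwoWayAnova:
    def test_constant_values_flagged_degenerate(self):
        table = make_table({g: np.full((3, 1), 7.0)
                            for g in [("male", "naive"), ("female", "naive"),
                                      ("male", "trained"), ("female", "trained")]})
        res = two_way_anova(table, "REG0")
        assert res.degenerate
        assert np.isnan(res.F_training) and np.isnan(res.p_training)

    def test_pure_training_shift(self):
        naive = [[10.0], [11.0], [12.0]]
        trained = [[40.0], [41.0], [42.0]]
        table = make_table({("male", "naive"): naive, ("female", "naive"): naive,
                            ("male", "trained"): trained, ("female", "trained"): trained})
        res = two_way_anova(table, "REG0")
        assert res.F_training > 100
        assert res.F_sex == pytest.approx(0.0, abs=1e-10)
        assert res.F_interaction == pytest.approx(0.0, abs=1e-10)
        assert res.df_error == table.n_animals - 4

    def test_matches_design_matrix_oracle_unbalanced(self, unbalanced_table):
        table = unbalanced_table
        for region in table.region_order[:3]:
            res = two_way_anova(table, region)
            y = table.counts[region].to_numpy()
            oracle = brute_anova_type3(
                y, female=(table.factors["sex"] == "female").to_numpy(),
                trained=(table.factors["condition"] == "trained").to_numpy())
            assert res.F_training == pytest.approx(oracle["F_training"], rel=1e-8)
            assert res.F_sex == pytest.approx(oracle["F_sex"], rel=1e-8)
            assert res.F_interaction == pytest.approx(oracle["F_interaction"], rel=1e-8)
            assert res.mse == pytest.approx(oracle["mse"], rel=1e-8)

    def test_matches_statsmodels_type3_formula_fit(self, unbalanced_table):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        table = unbalanced_table
        region = table.region_order[0]
        res = two_way_anova(table, region)
        df = pd.DataFrame({"y": table.counts[region],
                           "sex": table.factors["sex"],
                           "cond": table.factors["condition"]})
        tab = anova_lm(smf.ols("y ~ C(sex, Sum)*C(cond, Sum)", data=df).fit(), typ=3)
        assert res.F_sex == pytest.approx(tab.loc["C(sex, Sum)", "F"], rel=1e-8)
        assert res.F_training == pytest.approx(tab.loc["C(cond, Sum)", "F"], rel=1e-8)
        assert res.F_interaction == pytest.approx(
            tab.loc["C(sex, Sum):C(cond, Sum)", "F"], rel=1e-8)

    def test_balanced_design_type1_equals_type3(self, balanced_table):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        region = "REG1"
        res = two_way_anova(balanced_table, region)
        df = pd.DataFrame({"y": balanced_table.counts[region],
                           "sex": balanced_table.factors["sex"],
                           "cond": balanced_table.factors["condition"]})
        tab1 = anova_lm(smf.ols("y ~ C(sex)*C(cond)", data=df).fit(), typ=1)
        assert res.F_sex == pytest.approx(tab1.loc["C(sex)", "F"], rel=1e-8)
        assert res.F_training == pytest.approx(tab1.loc["C(cond)", "F"], rel=1e-8)

    def test_invariant_to_animal_and_region_order(self, unbalanced_table):
        table = unbalanced_table
        res = two_way_anova(table, "REG2")
        perm = table.subset(animals=table.animals[::-1],
                            regions=table.region_order[::-1])
        res_perm = two_way_anova(perm, "REG2")
        assert res.p_training == pytest.approx(res_perm.p_training)
        assert res.p_interaction == pytest.approx(res_perm.p_interaction)

    def test_empty_cell_rejected(self):
        table = make_table({("male", "naive"): np.ones((3, 1)) * [[1], [2], [3]],
                            ("female", "naive"): [[2], [3], [4]],
                            ("male", "trained"): [[5], [6], [7]]})
        with pytest.raises(ValidationError, match="cell"):
            two_way_anova(table, "REG0")


class TestFishersLSD:
    def test_identical_means_give_t0_p1(self, unbalanced_table):
        table = unbalanced_table
        region = table.region_order[0]
        # overwrite the two trained cells with identical values
        for g in [("male", "trained"), ("female", "trained")]:
            table.counts.loc[table.group_animals(g), region] = [30.0, 31.0, 32.0, 33.0][:len(table.group_animals(g))]
        table.counts.loc[table.group_animals(("female", "trained"))[:3], region] = [30.0, 31.0, 32.0]
        a = two_way_anova(table, region)
        mt = table.counts.loc[table.group_animals(("male", "trained")), region].mean()
        ft = table.counts.loc[table.group_animals(("female", "trained")), region]
        table.counts.loc[table.group_animals(("female", "trained")), region] = \
            ft - ft.mean() + mt  # equalize means exactly
        a = two_way_anova(table, region)
        c = fishers_lsd(a, table, region, ("male", "trained"), ("female", "trained"))
        assert c.t == pytest.approx(0.0, abs=1e-10)
        assert c.p == pytest.approx(1.0)

    def test_unit_t_construction_and_arithmetic_oracle(self, unbalanced_table):
        table = unbalanced_table
        region = table.region_order[1]
        a = two_way_anova(table, region)
        ga, gb = ("male", "trained"), ("female", "trained")
        c = fishers_lsd(a, table, region, ga, gb)
        xa = table.counts.loc[table.group_animals(ga), region].to_numpy()
        xb = table.counts.loc[table.group_animals(gb), region].to_numpy()
        se = np.sqrt(a.mse * (1 / len(xa) + 1 / len(xb)))
        assert c.t == pytest.approx((xa.mean() - xb.mean()) / se, rel=1e-10)
        from scipy import stats
        assert c.p == pytest.approx(2 * stats.t.sf(abs(c.t), a.df_error), rel=1e-10)
        # unit construction: shift group a so the difference equals one se
        shifted = table.counts.copy()
        shifted.loc[table.group_animals(ga), region] = xa - xa.mean() + xb.mean() + se
        table2 = table.subset()
        table2.counts = shifted
        a2 = two_way_anova(table2, region)
        c2 = fishers_lsd(a2, table2, region, ga, gb)
        # mse changes with the shift, so compare against its own se
        se2 = np.sqrt(a2.mse * (1 / len(xa) + 1 / len(xb)))
        assert c2.mean_diff == pytest.approx(se)
        assert c2.t == pytest.approx(se / se2)


class TestScreen:
    def test_recovers_planted_training_regions(self):
        n = 112
        spec = CohortSpec(n_regions=n,
                          n_per_group={g: 50 for g in [("male", "naive"),
                                                       ("female", "naive"),
                                                       ("male", "trained"),
                                                       ("female", "trained")]},
                          seed=9)
        res = screen_all_regions(generate_cohort(spec))
        n_train = res.counts["n_training"]
        assert 88 <= n_train <= 98  # 93 planted, power ~1, few false positives

    def test_single_region_table(self, balanced_table):
        res = screen_all_regions(balanced_table.subset(regions=["REG0"]))
        assert len(res.anovas) == 1

    def test_contrast_gating_on_interaction(self, unbalanced_table):
        gated = screen_all_regions(unbalanced_table, gate_on_interaction=True)
        ungated = screen_all_regions(unbalanced_table, gate_on_interaction=False)
        sig = set(gated.significant_regions("interaction"))
        assert {c.region for c in gated.contrasts} == sig
        assert len(ungated.contrasts) == unbalanced_table.n_regions

    def test_fdr_adds_adjusted_columns(self, unbalanced_table):
        res = screen_all_regions(unbalanced_table, fdr=True)
        assert "p_training_fdr" in res.frame.columns
        # BH-adjusted p-values never fall below raw ones
        assert (res.frame["p_training_fdr"] >= res.frame["p_training"] - 1e-12).all()

    def test_summary_mentions_counts(self, unbalanced_table):
        text = screen_all_regions(unbalanced_table).summary()
        assert "main effect of training" in text
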