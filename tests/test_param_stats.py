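"""Mixed-model recovery of planted hyperparameter effects."""

import numpy as np
import pytest
from scipy import stats

from pentail.param_stats import anova, fit_lmem, posthoc, simulate_cv_table

SMALL_GRID = dict(
    n_obs_levels=(10, 30),
    n_pc_levels=(4, 8, 32, 64),
    n_layers_levels=(1, 2),
    width_levels=("mean", "sum"),
    dropout_levels=(0.0, 0.2),
)


class TestPlantedEffectRecovery:
    def test_npc_effect_detected_null_factors_quiet(self):
        df = simulate_cv_table(seed=3, effect_npc=0.1)
        fitted = fit_lmem(df, "btmma", "lstm")
        table = anova(fitted).set_index("factor")
        assert table.loc["n_pc", "p"] < 1e-3
        for factor in ("n_obs", "n_layers", "node_rule", "dropout"):
            assert table.loc[factor, "p"] >= 1e-3

    def test_constant_metric_yields_no_signal(self):
        # all-null simulation: no factor reaches significance
        df = simulate_cv_table(seed=4, effect_npc=0.0, **SMALL_GRID)
        table = anova(fit_lmem(df, "nmma", "lstm")).set_index("factor")
        assert (table["p"] >= 1e-3).all()
        assert (table["F"] < 10).all()

    def test_anova_df_equals_levels_minus_one(self):
        df = simulate_cv_table(seed=5, effect_npc=0.05)
        table = anova(fit_lmem(df, "btmma", "lstm")).set_index("factor")
        assert table.loc["n_obs", "df"] == 2
        assert table.loc["n_pc", "df"] == 8
        assert table.loc["n_layers", "df"] == 2
        assert table.loc["node_rule", "df"] == 2
        assert table.loc["dropout", "df"] == 1

    def test_cnn_factor_layout(self):
        df = simulate_cv_table(seed=6, family="cnn",
                               n_pc_levels=(4, 8, 16, 32, 64, 128, 256, "none"))
        table = anova(fit_lmem(df, "btmma", "cnn")).set_index("factor")
        assert table.loc["n_pc", "df"] == 7
        assert table.loc["first_filters", "df"] == 3

    def test_refit_is_deterministic(self):
        df = simulate_cv_table(seed=7, effect_npc=0.1, **SMALL_GRID)
        t1 = anova(fit_lmem(df, "btmma", "lstm"))
        t2 = anova(fit_lmem(df, "btmma", "lstm"))
        np.testing.assert_allclose(t1["F"], t2["F"])

    def test_estimates_invariant_to_row_order(self):
        df = simulate_cv_table(seed=8, effect_npc=0.1, **SMALL_GRID)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        f1 = fit_lmem(df, "btmma", "lstm")
        f2 = fit_lmem(shuffled, "btmma", "lstm")
        np.testing.assert_allclose(
            f1.result.fe_params.sort_index(), f2.result.fe_params.sort_index(),
            atol=1e-8,
        )


class TestNullCalibration:
    def test_null_factor_pvalues_uniform(self):
        # p-values of a truly null factor across replicates look uniform
        pvals = []
        for rep in range(40):
            df = simulate_cv_table(seed=1000 + rep, effect_npc=0.0, **SMALL_GRID)
            table = anova(fit_lmem(df, "btmma", "lstm")).set_index("factor")
            pvals.append(table.loc["n_layers", "p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestVarianceRecovery:
    def test_pen_variance_recovered(self):
        planted = 0.01**2
        estimates = [
            fit_lmem(
                simulate_cv_table(seed=2000 + rep, pen_sd=0.01, **SMALL_GRID),
                "btmma", "lstm",
            ).group_variance()
            for rep in range(50)
        ]
        assert abs(np.mean(estimates) - planted) / planted < 0.5


class TestPosthoc:
    def test_planted_ordering_recovered(self):
        # n_pc >= 32 lifted by +0.02: high-vs-low contrasts significant
        df = simulate_cv_table(seed=9, effect_npc=0.02, **SMALL_GRID)
        fitted = fit_lmem(df, "btmma", "lstm")
        table = posthoc(fitted, "n_pc").set_index(["level_a", "level_b"])
        row = table.loc[("4.0", "32.0")] if ("4.0", "32.0") in table.index \
            else table.loc[("4", "32")]
        assert row["estimate"] < 0  # level 4 below level 32
        assert row["p_adj"] < 0.01

    def test_null_pairs_not_significant(self):
        df = simulate_cv_table(seed=10, effect_npc=0.0, **SMALL_GRID)
        fitted = fit_lmem(df, "btmma", "lstm")
        table = posthoc(fitted, "node_rule")
        assert (np.abs(table["estimate"]) < 0.01).all()
        assert (table["p_adj"] > 0.05).all()

    def test_contrasts_antisymmetric_in_coefficients(self):
        df = simulate_cv_table(seed=11, effect_npc=0.05, **SMALL_GRID)
        fitted = fit_lmem(df, "btmma", "lstm")
        table = posthoc(fitted, "n_obs")
        beta = fitted.result.fe_params
        for _, row in table.iterrows():
            ca = beta.get(f"C(n_obs)[T.{row['level_a']}]", 0.0)
            cb = beta.get(f"C(n_obs)[T.{row['level_b']}]", 0.0)
            assert row["estimate"] == pytest.approx(ca - cb, abs=1e-12)

    def test_single_level_factor_rejected(self):
        df = simulate_cv_table(seed=12, effect_npc=0.0, **SMALL_GRID)
        fitted = fit_lmem(df, "btmma", "lstm")
        with pytest.raises(ValueError):
            posthoc(fitted, "fold_id")
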