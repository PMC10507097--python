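import itertools

import numpy as np
import pandas as pd
import pytest

import phenoclim as pc
from phenoclim.growth import DESIGNS, DesignError, logistic3, logistic4


def make_blue_table(mu=100.0, g_effects=(0.0, 10.0, -10.0), rep_effects=(2.0, -2.0),
                    noise_sd=1.0, seed=0, n_pos=4):
    """Small balanced one-date trial with planted genotype + replicate effects."""
    rng = np.random.default_rng(seed)
    rows = []
    for gi, g in enumerate(g_effects):
        for ri, r in enumerate(rep_effects):
            for p in range(n_pos):
                rows.append(
                    {
                        "genotype": f"g{gi}",
                        "environment": "e1",
                        "das": 50,
                        "replicate": ri + 1,
                        "position": p + 1,
                        "plant_height": mu + g + r + rng.normal(0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)


class TestBlues:
    def test_balanced_zero_variance_equals_genotype_means(self):
        table = make_blue_table(rep_effects=(0.0, 0.0), noise_sd=0.0)
        res = pc.estimate_blues(table, DESIGNS["field"], date=50)
        means = table.groupby("genotype")["plant_height"].mean()
        for g in means.index:
            assert res.blues[g] == pytest.approx(means[g], abs=1e-6)

    def test_blue_invariance_under_constant_shift(self):
        table = make_blue_table(seed=3)
        res = pc.estimate_blues(table, DESIGNS["field"], date=50)
        shifted = table.copy()
        shifted["plant_height"] += 7.0
        res2 = pc.estimate_blues(shifted, DESIGNS["field"], date=50)
        for g in res.blues.index:
            assert res2.blues[g] - res.blues[g] == pytest.approx(7.0, abs=1e-6)

    def test_planted_effects_recovered_within_two_se(self):
        hits = total = 0
        for seed in range(10):
            table = make_blue_table(seed=seed)
            res = pc.estimate_blues(table, DESIGNS["field"], date=50)
            centered = res.blues - res.blues.mean()
            truth = pd.Series([0.0, 10.0, -10.0], index=["g0", "g1", "g2"])
            for g in truth.index:
                total += 1
                hits += abs(centered[g] - truth[g]) <= 2.0 * res.se[g]
        assert hits / total >= 0.95

    def test_confounded_factor_is_design_error(self):
        table = make_blue_table()
        table["position"] = table["genotype"].str.replace("g", "p")
        with pytest.raises(DesignError, match="confounded"):
            pc.estimate_blues(table, DESIGNS["field"], date=50)

    def test_missing_random_factor_column_is_design_error(self):
        table = make_blue_table().drop(columns=["position"])
        with pytest.raises(DesignError, match="missing column"):
            pc.estimate_blues(table, DESIGNS["field"], date=50)

    def test_sparse_genotype_flagged(self):
        table = make_blue_table()
        keep_one = table[table.genotype == "g2"].index[0]
        table = table[(table.genotype != "g2") | (table.index == keep_one)]
        res = pc.estimate_blues(table, DESIGNS["field"], date=50)
        assert "g2" in res.flagged


class TestLogisticFit:
    def test_noiseless_curve_recovered(self):
        t = np.arange(7, 116, 3.5)
        y = logistic3(t, 220.0, 68.0, 9.0)
        popt, _, resid = pc.fit_logistic_curve(t, y)
        np.testing.assert_allclose(popt, [220.0, 68.0, 9.0], rtol=1e-5)
        assert np.abs(resid).max() < 1e-5

    def test_noiseless_four_parameter_curve_recovered(self):
        t = np.arange(0, 40, 1.0)
        y = logistic4(t, 3.0, 25.0, 18.0, 4.0)
        popt, _, _ = pc.fit_logistic_curve(t, y, n_params=4)
        np.testing.assert_allclose(popt, [3.0, 25.0, 18.0, 4.0], rtol=1e-4)

    def test_population_fit_recovers_environment_params(
        self, population_fit, phenotypes
    ):
        _, truth = phenotypes
        for env, (asym, xmid, scal) in truth["env_params"].items():
            assert population_fit.fixed["Asym"][env] == pytest.approx(asym, rel=0.03)
            assert population_fit.fixed["xmid"][env] == pytest.approx(xmid, abs=2.0)

    def test_genotype_random_deviations_centred_and_correlated_with_truth(
        self, population_fit, phenotypes
    ):
        _, truth = phenotypes
        for param, key in [("Asym", "genotype_asym"), ("xmid", "genotype_xmid")]:
            devs = population_fit.random[param]
            assert devs, f"no random deviations for {param}"
            vals = np.array([devs[g] for g in population_fit.genotypes])
            assert abs(vals.mean()) < 0.15 * (np.abs(vals).max() + 1e-9)
            tr = np.array([truth[key][g] for g in population_fit.genotypes])
            assert np.corrcoef(vals, tr)[0, 1] > 0.9

    def test_scal_has_no_genotype_random_effect(self, population_fit):
        assert population_fit.random["scal"] == {}

    def test_curve_at_xmid_is_half_asymptote(self, population_fit):
        for env in population_fit.environments:
            asym = population_fit.fixed["Asym"][env]
            xmid = population_fit.fixed["xmid"][env]
            assert population_fit.curve(env, xmid) == pytest.approx(asym / 2.0)

    def test_conditional_at_least_marginal_determination(self, population_fit):
        for r2 in population_fit.diagnostics["determination"].values():
            assert r2["conditional"] >= r2["marginal"]

    def test_ljung_box_diagnostic_reported(self, population_fit):
        assert population_fit.diagnostics["ljung_box_lags"] == 10
        assert population_fit.diagnostics["ljung_box_stat_mean"] > 0


class TestDerivativeAndPrediction:
    def test_speed_at_xmid_is_25_over_scal(self, population_fit):
        env = population_fit.environments[0]
        xmid = population_fit.fixed["xmid"][env]
        scal = population_fit.fixed["scal"][env]
        speed = pc.growth_speed_curve(population_fit, env, xmid)
        assert speed == pytest.approx(25.0 / scal)

    def test_speed_vanishes_in_the_tails(self, population_fit):
        env = population_fit.environments[0]
        tails = pc.growth_speed_curve(population_fit, env, np.array([-500.0, 800.0]))
        assert np.all(tails < 1e-8)

    def test_full_trace_matches_finite_difference_oracle(self, population_fit):
        env = population_fit.environments[0]
        asym = population_fit.fixed["Asym"][env]
        x = np.linspace(20.0, 110.0, 50)
        h = 1e-5
        fd = (population_fit.curve(env, x + h) - population_fit.curve(env, x - h)) / (2 * h)
        oracle = 100.0 * fd / asym
        np.testing.assert_allclose(
            pc.growth_speed_curve(population_fit, env, x), oracle, rtol=1e-6
        )

    def test_height_at_own_xmid_is_half_genotype_asymptote(self, population_fit):
        g = population_fit.genotypes[0]
        env = population_fit.environments[0]
        asym, xmid, _ = population_fit.params_for(g, env)
        assert pc.height_at_time(population_fit, g, env, xmid) == pytest.approx(asym / 2)

    def test_height_saturates_at_genotype_asymptote(self, population_fit):
        g = population_fit.genotypes[0]
        env = population_fit.environments[0]
        asym, _, _ = population_fit.params_for(g, env)
        assert pc.height_at_time(population_fit, g, env, 1e6) == pytest.approx(asym)

    def test_height_at_68_matches_direct_evaluation(self, population_fit):
        g = population_fit.genotypes[2]
        env = population_fit.environments[1]
        pars = population_fit.params_for(g, env)
        assert pc.height_at_time(population_fit, g, env, 68.0) == pytest.approx(
            logistic3(68.0, *pars)
        )


def brute_force_complete_linkage(X, labels):
    """Exhaustive agglomeration oracle: complete linkage, Manhattan distance."""
    clusters = [[i] for i in range(len(labels))]
    merges = []
    def dist(a, b):
        return max(
            np.abs(X[i] - X[j]).sum() for i in a for j in b
        )
    while len(clusters) > 1:
        best = min(
            itertools.combinations(range(len(clusters)), 2),
            key=lambda ij: dist(clusters[ij[0]], clusters[ij[1]]),
        )
        i, j = best
        merges.append((sorted(clusters[i] + clusters[j]), dist(clusters[i], clusters[j])))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [
            clusters[i] + clusters[j]
        ]
    return merges


class TestClustering:
    def _matrix(self, seed=0, n_geno=11, n_env=6):
        rng = np.random.default_rng(seed)
        data = rng.normal(100, 20, (n_geno, n_env))
        return pd.DataFrame(
            data,
            index=[f"g{i}" for i in range(n_geno)],
            columns=[f"e{j}" for j in range(n_env)],
        )

    def test_duplicated_environment_merges_first(self):
        mat = self._matrix()
        mat["e_dup"] = mat["e0"]
        res = pc.cluster_environments(mat)
        first = res.linkage[0]
        merged = {res.environments[int(first[0])], res.environments[int(first[1])]}
        assert merged == {"e0", "e_dup"}
        assert first[2] == pytest.approx(0.0)

    def test_planted_two_clades_recovered(self):
        rng = np.random.default_rng(1)
        profile_a = rng.normal(0, 1, 11)
        profile_b = -profile_a
        cols = {}
        for j in range(3):
            cols[f"a{j}"] = 100 + 30 * profile_a + rng.normal(0, 1, 11)
        for j in range(3):
            cols[f"b{j}"] = 100 + 30 * profile_b + rng.normal(0, 1, 11)
        mat = pd.DataFrame(cols, index=[f"g{i}" for i in range(11)])
        res = pc.cluster_environments(mat)
        two = res.cut(2)
        clade_a = {e for e, c in two.items() if c == two["a0"]}
        assert clade_a == {"a0", "a1", "a2"}

    def test_merge_heights_match_exhaustive_oracle(self):
        mat = self._matrix(seed=4, n_env=6)
        res = pc.cluster_environments(mat)
        z = res.standardized
        oracle = brute_force_complete_linkage(z.T.to_numpy(), res.environments)
        np.testing.assert_allclose(
            sorted(res.merge_heights), sorted(h for _, h in oracle), rtol=1e-9
        )

    def test_constant_row_dropped_with_warning(self):
        mat = self._matrix()
        mat.loc["g0"] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            res = pc.cluster_environments(mat)
        assert "g0" in res.dropped_rows

    def test_missing_cells_rejected(self):
        mat = self._matrix()
        mat.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            pc.cluster_environments(mat)


class TestTassel:
    def test_step_function_localizes_xmid(self):
        days = np.arange(10, 100, 3.5)
        rows = []
        for env, step in [("e1", 50.0)]:
            pct = np.where(days >= step, 100.0, 0.0)
            rows.append(pd.DataFrame({"environment": env, "das": days, "percent": pct}))
        res = pc.fit_tassel_model(pd.concat(rows, ignore_index=True))
        assert abs(res.params.loc["e1", "xmid"] - 50.0) <= 3.5

    def test_planted_offsets_recovered(self):
        cfg = pc.TasselGenConfig(
            env_median_das={"early": 50.0, "late": 70.0}, onset_scale=3.0
        )
        data = pc.generate_tassel(cfg, seed=4)
        res = pc.fit_tassel_model(data)
        offset = res.params.loc["late", "xmid"] - res.params.loc["early", "xmid"]
        assert offset == pytest.approx(20.0, abs=2.0)

    def test_anova_cultivation_df_with_seven_environments(self):
        data = pc.generate_tassel(seed=4)
        res = pc.fit_tassel_model(data)
        assert res.anova_fitted.loc["C(environment)", "df"] == 6
        # residuals carry no systematic cultivation signal
        assert res.anova_residuals.loc["C(environment)", "PR(>F)"] > 0.05

    def test_percentages_out_of_range_rejected(self):
        bad = pd.DataFrame({"environment": "e", "das": [1, 2], "percent": [0.0, 120.0]})
        with pytest.raises(ValueError):
            pc.fit_tassel_model(bad)

    def test_environment_with_few_points_excluded(self):
        days = np.arange(10, 100, 3.5)
        good = pd.DataFrame(
            {"environment": "ok", "das": days,
             "percent": np.where(days >= 50, 100.0, 0.0)}
        )
        bad = pd.DataFrame({"environment": "thin", "das": [10, 20, 30],
                            "percent": [0.0, 50.0, 100.0]})
        res = pc.fit_tassel_model(pd.concat([good, bad], ignore_index=True))
        assert "thin" in res.excluded


class TestRepeatability:
    def test_near_zero_residual_variance_gives_r_near_one(self):
        cfg = pc.RepeatabilityGenConfig(
            residual_sd=0.01, genotype_experiment_sd=0.0, genotype_time_sd=0.0,
            n_times=4, n_experiments=3,
        )
        table = pc.generate_repeatability_table(cfg, seed=0)
        res = pc.repeatability(table)
        assert res.repeatability > 0.99

    def test_planted_half_recovered(self):
        table = pc.generate_repeatability_table(seed=5)
        res = pc.repeatability(table)
        assert res.repeatability == pytest.approx(0.5, abs=0.2)  # single seed

    def test_conditional_at_least_marginal(self):
        table = pc.generate_repeatability_table(seed=5)
        res = pc.repeatability(table)
        assert res.r2_conditional >= res.r2_marginal

    def test_degenerate_inputs_rejected(self):
        table = pc.generate_repeatability_table(seed=5)
        with pytest.raises(DesignError):
            pc.repeatability(table[table.experiment == "e1"])


class TestVarianceDecomposition:
    def test_only_genotype_and_residual_planted(self):
        cfg = pc.HomogeneityGenConfig(row_effect_sd=0.0)
        table = pc.generate_homogeneity_trial(cfg, seed=3)
        dec = pc.variance_decomposition(table, n_boot=30, seed=3)
        for factor in ("preculture", "column", "row", "replicate", "soil"):
            assert dec.shares[factor] < 0.05
            assert dec.ci[factor][0] <= 0.02  # interval reaches down to ~zero

    def test_shares_sum_to_one_and_nonnegative(self):
        table = pc.generate_homogeneity_trial(seed=3)
        dec = pc.variance_decomposition(table, n_boot=10, seed=3)
        assert sum(dec.shares.values()) == pytest.approx(1.0, abs=1e-6)
        assert all(v >= 0.0 for v in dec.shares.values())


class TestYield:
    def _yield_table(self, g_sd=8.0, seed=0, n_env=3):
        rng = np.random.default_rng(seed)
        genos = [f"g{i}" for i in range(8)]
        g_eff = rng.normal(0, g_sd, len(genos))
        rows = []
        for e in range(n_env):
            env_eff = rng.normal(0, 5)
            for gi, g in enumerate(genos):
                for rep in (1, 2):
                    for pos in (1, 2, 3):
                        rows.append(
                            {
                                "genotype": g,
                                "environment": f"env{e}",
                                "replicate": rep,
                                "position": pos,
                                "grain_weight": 100 + env_eff + g_eff[gi]
                                + rng.normal(0, 3),
                            }
                        )
        return pd.DataFrame(rows), dict(zip(genos, g_eff))

    def test_zero_genotype_variance_fully_shrinks(self):
        table, _ = self._yield_table(g_sd=0.0, seed=1)
        res = pc.yield_components(table, "grain_weight", DESIGNS["field"])
        for env in res.blups.columns:
            col = res.blups[env].dropna()
            assert col.std() < 0.75  # strong shrinkage toward the grand mean

    def test_planted_effects_correlate_with_blups(self):
        table, truth = self._yield_table(g_sd=8.0, seed=2)
        res = pc.yield_components(table, "grain_weight", DESIGNS["field"])
        for env in res.blups.columns:
            est = res.blups[env]
            tr = pd.Series(truth).reindex(est.index)
            assert np.corrcoef(est, tr)[0, 1] > 0.9

    def test_identical_environments_nonsignificant_contrasts(self):
        table, _ = self._yield_table(seed=3, n_env=1)
        dup = table.copy()
        dup["environment"] = "env_dup"
        res = pc.yield_components(
            pd.concat([table, dup], ignore_index=True), "grain_weight", DESIGNS["field"]
        )
        assert (res.contrasts["p_tukey"] > 0.05).all()
        assert res.contrasts["difference"].abs().max() < 1.0


class TestParameterContrasts:
    def test_seven_environments_give_21_contrasts_per_parameter(self, population_fit):
        contrasts = pc.parameter_contrasts(population_fit)
        per_param = contrasts.groupby("parameter").size()
        assert (per_param == 21).all()

    def test_shifted_environment_detected(self, population_fit, phenotypes):
        _, truth = phenotypes
        contrasts = pc.parameter_contrasts(population_fit)
        xm = contrasts[contrasts.parameter == "xmid"]
        # glasshouse inflects ~30 days earlier than the field seasons: every
        # glasshouse-vs-field contrast must be significant
        gg = xm[(xm.a == "glasshouse") | (xm.b == "glasshouse")]
        gg = gg[gg.a.str.startswith("field") | gg.b.str.startswith("field")]
        assert gg["significant"].all()
        # field seasons planted within ~2.5 DAS of each other: differences small
        ff = xm[xm.a.str.startswith("field") & xm.b.str.startswith("field")]
        assert ff["difference"].abs().max() < 5.0
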