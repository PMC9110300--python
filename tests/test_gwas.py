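"""Association models: centering algebra, QC rules, estimator behaviour and
cluster-robust standard errors (statsmodels as the independent oracle)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sibgwas as sg
from sibgwas.gwas import center_genotypes


class TestCentering:
    @pytest.mark.parametrize("genos,mean,devs", [
        ([2, 1], 1.5, [0.5, -0.5]),
        ([1, 1], 1.0, [0.0, 0.0]),
        ([0, 1, 2], 1.0, [-1.0, 0.0, 1.0]),
    ])
    def test_worked_examples(self, genos, mean, devs):
        cg = center_genotypes(np.array(genos)[:, None], ["f"] * len(genos))
        assert cg.family_mean[:, 0] == pytest.approx([mean] * len(genos))
        assert cg.centered[:, 0] == pytest.approx(devs)

    def test_singleton_sibship_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            center_genotypes(np.array([[1], [2], [0]]), ["a", "a", "b"])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(2, 5), min_size=1, max_size=6),
           st.integers(0, 2**31 - 1))
    def test_centered_values_sum_to_zero_exactly(self, sizes, seed):
        rng = np.random.default_rng(seed)
        fids = np.repeat([f"f{i}" for i in range(len(sizes))], sizes)
        g = rng.integers(0, 3, size=(len(fids), 3))
        cg = center_genotypes(g, fids)
        sums = pd.DataFrame(cg.centered).groupby(fids).sum().to_numpy()
        assert np.all(np.abs(sums) < 1e-12)  # machine precision
        assert np.all(cg.family_mean >= np.repeat(
            pd.DataFrame(g).groupby(fids).min().to_numpy(), sizes, axis=0))


class TestQcRules:
    def test_missingness_rule(self, tiny_cohort):
        y = tiny_cohort.phenotypes["trait"].copy()
        y.iloc[0] = np.nan                       # sibship of 2, one missing
        tiny_cohort.phenotypes["trait"] = y
        out = sg.apply_missingness_rule(tiny_cohort, "trait")
        assert out.phenotypes["trait"].iloc[:2].isna().all()
        assert out.phenotypes["trait"].iloc[2:].notna().all()

    def test_missingness_rule_keeps_pairs_in_trios(self):
        samples = pd.DataFrame({"IID": list("abc"), "FID": "f", "subpop": 0,
                                "sex": 0, "age": 50.0})
        cohort = sg.SibshipCohort(
            genotypes=np.zeros((3, 1), dtype=np.int8), samples=samples,
            variants=pd.DataFrame({"SNP": ["1:1:SNP"], "CHR": 1, "BP": 1,
                                   "EA": "A", "OA": "G", "MAF": 0.3,
                                   "INFO": 1.0}),
            phenotypes=pd.DataFrame({"t": [1.0, np.nan, 2.0]}))
        out = sg.apply_missingness_rule(cohort, "t")
        assert out.phenotypes["t"].notna().sum() == 2

    def test_missingness_rule_identity_when_complete(self, tiny_cohort):
        out = sg.apply_missingness_rule(tiny_cohort, "trait")
        pd.testing.assert_frame_equal(out.phenotypes, tiny_cohort.phenotypes)

    def test_unknown_phenotype_rejected(self, tiny_cohort):
        with pytest.raises(KeyError):
            sg.apply_missingness_rule(tiny_cohort, "nope")

    def test_qc_filter(self):
        table = pd.DataFrame({"SNP": list("abc"), "MAF": [0.005, 0.3, 0.3],
                              "INFO": [1.0, 0.2, 1.0]})
        out = sg.qc_filter_variants(table)
        assert list(out["SNP"]) == ["c"]
        full = pd.DataFrame({"SNP": list("ab"), "MAF": [0.3, 0.3],
                             "INFO": [1.0, 1.0]})
        pd.testing.assert_frame_equal(sg.qc_filter_variants(full), full)


@pytest.fixture(scope="module")
def oracle_cohort():
    cfg = sg.SimulationConfig(n_sibships=80, n_variants=4, n_pcs=2,
                              sibs_per_family={2: 0.6, 3: 0.4},
                              beta_direct=0.3, seed=30)
    return sg.simulate_cohort(cfg)


class TestAgainstStatsmodels:
    """Closed-form vectorised fits must equal full per-variant OLS."""

    def _sm_fit(self, y, x, groups, cluster):
        import statsmodels.api as smapi
        res = smapi.OLS(y, x).fit()
        if cluster:
            res = res.get_robustcov_results(cov_type="cluster",
                                            groups=groups,
                                            use_correction=False)
            g = len(np.unique(groups))
            return res.params, np.asarray(res.bse) * np.sqrt(g / (g - 1))
        return res.params, res.bse

    @pytest.mark.parametrize("se_type", ["cluster", "naive"])
    def test_population_model_matches_ols(self, oracle_cohort, se_type):
        cohort = oracle_cohort
        fit = sg.PopulationGwas(cohort, "trait", n_pcs=2,
                                se_type=se_type).fit()
        model = sg.PopulationGwas(cohort, "trait", n_pcs=2)
        rows = model._rows
        y = cohort.phenotypes["trait"].to_numpy()[rows]
        covars = cohort.samples[model.covariates].to_numpy()[rows]
        groups = pd.factorize(cohort.sibship_ids[rows])[0]
        for j in range(cohort.n_variants):
            x = np.column_stack([cohort.genotypes[rows, j].astype(float),
                                 np.ones(len(rows)), covars])
            params, bse = self._sm_fit(y, x, groups, se_type == "cluster")
            assert fit.table["BETA"][j] == pytest.approx(params[0], rel=1e-8)
            assert fit.table["SE"][j] == pytest.approx(bse[0], rel=1e-6)

    def test_within_sibship_model_matches_ols(self, oracle_cohort):
        cohort = oracle_cohort
        fit = sg.WithinSibshipGwas(cohort, "trait", n_pcs=2).fit()
        model = sg.WithinSibshipGwas(cohort, "trait", n_pcs=2)
        rows = model._rows
        y = cohort.phenotypes["trait"].to_numpy()[rows]
        covars = cohort.samples[model.covariates].to_numpy()[rows]
        groups = pd.factorize(cohort.sibship_ids[rows])[0]
        cg = center_genotypes(cohort.genotypes[rows], groups)
        for j in range(cohort.n_variants):
            x = np.column_stack([cg.centered[:, j], cg.family_mean[:, j],
                                 np.ones(len(rows)), covars])
            params, bse = self._sm_fit(y, x, groups, True)
            assert fit.table["BETA"][j] == pytest.approx(params[0], rel=1e-8)
            assert fit.table["SE"][j] == pytest.approx(bse[0], rel=1e-6)
            assert fit.table["FBETA"][j] == pytest.approx(params[1], rel=1e-8)
            assert fit.table["FSE"][j] == pytest.approx(bse[1], rel=1e-6)


class TestEstimatorBehaviour:
    def test_exact_linear_recovery(self, tiny_cohort):
        g = tiny_cohort.genotypes[:, 0].astype(float)
        sex = tiny_cohort.samples["sex"].to_numpy()
        tiny_cohort.phenotypes["lin"] = 2.0 * g + 0.5 * sex
        fit = sg.PopulationGwas(tiny_cohort, "lin", covariates=["sex"]).fit()
        assert fit.table["BETA"][0] == pytest.approx(2.0, abs=1e-9)

    def test_population_bias_equals_parental_effect(self, parental_cohort):
        # analytic oracle: cov(G_child, G_mother + G_father)/var(G_child) = 1
        cohort, cfg = parental_cohort
        pop = sg.PopulationGwas(cohort, "trait").fit()
        ws = sg.WithinSibshipGwas(cohort, "trait").fit()
        mc_se_pop = pop.table["SE"].mean() / np.sqrt(cohort.n_variants)
        mc_se_ws = ws.table["SE"].mean() / np.sqrt(cohort.n_variants)
        assert pop.table["BETA"].mean() == pytest.approx(
            cfg.beta_direct + cfg.eta_parental, abs=2.5 * mc_se_pop)
        assert ws.table["BETA"].mean() == pytest.approx(
            cfg.beta_direct, abs=2.5 * mc_se_ws)

    def test_family_coefficient_absorbs_parental_path(self, parental_cohort):
        cohort, cfg = parental_cohort
        ws = sg.WithinSibshipGwas(cohort, "trait").fit()
        # G^F tracks (G_m + G_f)/2, so its coefficient picks up ~2*eta + beta
        assert ws.table["FBETA"].mean() > ws.table["BETA"].mean() + 0.05

    def test_pure_family_effect_gives_zero_within_coefficient(self):
        cfg = sg.SimulationConfig(n_sibships=500, n_variants=3, seed=17)
        cohort = sg.simulate_cohort(cfg)
        cg = center_genotypes(cohort)
        cohort.phenotypes["fam"] = cg.family_mean[:, 0]
        ws = sg.WithinSibshipGwas(cohort, "fam", covariates=[]).fit()
        assert ws.table["BETA"][0] == pytest.approx(0.0, abs=1e-8)

    def test_pairs_equal_sib_difference_regression(self):
        cfg = sg.SimulationConfig(n_sibships=800, n_variants=5,
                                  beta_direct=0.2, seed=23)
        cohort = sg.simulate_cohort(cfg)
        ws = sg.WithinSibshipGwas(cohort, "trait", covariates=[]).fit()
        y = cohort.phenotypes["trait"].to_numpy().reshape(-1, 2)
        dy = y[:, 0] - y[:, 1]
        for j in range(5):
            g = cohort.genotypes[:, j].reshape(-1, 2).astype(float)
            dg = g[:, 0] - g[:, 1]
            slope = np.sum(dg * dy) / np.sum(dg * dg)
            assert ws.table["BETA"][j] == pytest.approx(slope, rel=1e-9)

    def test_monomorphic_variant_flagged_not_dropped(self, tiny_cohort):
        tiny_cohort.genotypes[:, 1] = 2
        fit = sg.PopulationGwas(tiny_cohort, "trait", covariates=[]).fit()
        assert np.isnan(fit.table["BETA"][1])
        assert fit.table["FLAG"][1] == "no_variance"
        assert len(fit.table) == 3

    def test_models_fit_identical_samples(self):
        cfg = sg.SimulationConfig(n_sibships=400, n_variants=5,
                                  sibs_per_family={2: 0.5, 3: 0.5}, seed=31)
        cohort = sg.simulate_cohort(cfg, missing_rate=0.15)
        cohort = sg.apply_missingness_rule(cohort, "trait")
        pop = sg.PopulationGwas(cohort, "trait").fit()
        ws = sg.WithinSibshipGwas(cohort, "trait").fit()
        assert pop.n == ws.n
        assert pop.n_sibships == ws.n_sibships


class TestStandardErrors:
    def test_clustered_se_calibrated_under_shared_environment(self):
        # each null variant is an independent replicate of the same design
        cfg = sg.SimulationConfig(n_sibships=1000, n_variants=800, n_causal=1,
                                  beta_direct=0.0, shared_env_var=0.4,
                                  seed=41)
        cohort = sg.simulate_cohort(cfg)
        fit = sg.PopulationGwas(cohort, "trait").fit()
        ratio = fit.table["SE"].mean() / fit.table["BETA"].std()
        assert 0.9 < ratio < 1.1

    def test_cryptic_relatedness_inflates_naive_population_only(self):
        cfg = sg.SimulationConfig(n_sibships=2000, n_variants=2500, n_causal=1,
                                  beta_direct=0.0, shared_env_var=0.5,
                                  cryptic_relatedness_frac=0.9, seed=43)
        cohort = sg.simulate_cohort(cfg)
        naive = sg.PopulationGwas(cohort, "trait", se_type="naive").fit()
        ws = sg.WithinSibshipGwas(cohort, "trait").fit()
        assert (naive.table["P"] < 0.05).mean() > 0.065
        assert 0.035 < (ws.table["P"] < 0.05).mean() < 0.068

    def test_effective_n_column_close_to_n_for_independent_rows(self):
        cfg = sg.SimulationConfig(n_sibships=3000, n_variants=20, n_causal=1,
                                  beta_direct=0.0, seed=47)
        cohort = sg.simulate_cohort(cfg)
        fit = sg.PopulationGwas(cohort, "trait").fit()
        med = np.median(fit.table["EFF_N"])
        # siblings are genetically clustered, so a modest deficit is expected
        assert 0.8 * fit.n < med < 1.1 * fit.n
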