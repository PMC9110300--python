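"""Simulator behaviour: mating structure, Mendelian transmission, phenotypes,
summary-statistic and SDS generators."""

import numpy as np
import pandas as pd
import pytest

import sibgwas as sg
from sibgwas.config import LdscSimConfig
from sibgwas.simulate import _mendelian_children, simulate_ldsc_summary


def _single_variant_config(am_corr, n_sibships=10_000, seed=1):
    # one causal variant carrying (almost) all phenotype variance
    maf = 0.3
    beta = 1.0 / np.sqrt(2 * maf * (1 - maf))
    return sg.SimulationConfig(n_sibships=n_sibships, n_variants=1, n_causal=1,
                               maf_range=(maf, maf + 1e-9), beta_direct=beta,
                               am_corr=am_corr, seed=seed)


class TestMating:
    def test_random_mating_mates_uncorrelated(self):
        pool = sg.simulate_parent_pool(_single_variant_config(0.0))
        r = np.corrcoef(pool.father_genotypes[:, 0],
                        pool.mother_genotypes[:, 0])[0, 1]
        assert abs(r) < 0.03

    def test_assortative_mating_genotype_correlation(self):
        pool = sg.simulate_parent_pool(_single_variant_config(0.4))
        r = np.corrcoef(pool.father_genotypes[:, 0],
                        pool.mother_genotypes[:, 0])[0, 1]
        assert r == pytest.approx(0.4, abs=0.05)

    def test_mate_phenotype_correlation_hits_target(self):
        cfg = sg.SimulationConfig(n_sibships=6000, n_variants=50,
                                  beta_direct=0.1, am_corr=0.4, seed=5)
        pool = sg.simulate_parent_pool(cfg)
        assert pool.mate_phenotype_correlation() == pytest.approx(0.4, abs=0.05)

    def test_am_corr_one_rejected(self):
        with pytest.raises(ValueError):
            sg.SimulationConfig(am_corr=1.0)


class TestTransmission:
    def test_homozygous_parents_force_children(self):
        rng = np.random.default_rng(0)
        gf = np.full((50, 4), 2, dtype=np.int8)
        kids = _mendelian_children(gf, gf, rng)
        assert (kids == 2).all()

    def test_het_by_homref_cross_gives_mendelian_ratio(self):
        rng = np.random.default_rng(1)
        n = 20_000
        kids = _mendelian_children(np.ones((n, 1)), np.zeros((n, 1)), rng)
        vals, counts = np.unique(kids, return_counts=True)
        assert set(vals) == {0, 1}
        assert counts[0] / n == pytest.approx(0.5, abs=0.02)

    def test_allele_frequency_conservation(self):
        cfg = sg.SimulationConfig(n_sibships=4000, n_variants=40, seed=9)
        pool = sg.simulate_parent_pool(cfg)
        cohort = sg.simulate_sibships(pool)
        p_cfg = pool.variants["EAF_TRUE"].to_numpy()
        p_child = cohort.genotypes.mean(axis=0) / 2
        se = np.sqrt(p_cfg * (1 - p_cfg) / (2 * cohort.n_individuals))
        assert (np.abs(p_child - p_cfg) < 3.5 * se).mean() > 0.95

    def test_sibling_genotype_correlation_random_mating(self):
        cfg = _single_variant_config(0.0, n_sibships=10_000, seed=3)
        cohort = sg.simulate_sibships(sg.simulate_parent_pool(cfg))
        g = cohort.genotypes[:, 0].reshape(-1, 2)
        r = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
        assert r == pytest.approx(0.5, abs=0.02)

    def test_sibling_correlation_raised_by_assortment(self):
        # exact oracle: cov(s1, s2) = var((G_f + G_m)/2), transmission noise
        # adds E[pq] to var(child), so r_sib = (1 + r_mate) / (2 + r_mate)
        cfg = _single_variant_config(0.4, n_sibships=10_000, seed=3)
        pool = sg.simulate_parent_pool(cfg)
        cohort = sg.simulate_sibships(pool)
        r_mate = np.corrcoef(pool.father_genotypes[:, 0],
                             pool.mother_genotypes[:, 0])[0, 1]
        g = cohort.genotypes[:, 0].reshape(-1, 2)
        r_sib = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
        assert r_sib > 0.55
        assert r_sib == pytest.approx((1 + r_mate) / (2 + r_mate), abs=0.03)

    def test_cryptic_relatedness_links_sibships(self):
        cfg = sg.SimulationConfig(n_sibships=400, n_variants=300,
                                  cryptic_relatedness_frac=0.5, seed=11)
        cohort = sg.simulate_sibships(sg.simulate_parent_pool(cfg))
        groups = cohort.parent_genotypes["founder_group"]
        n_links = 400 - len(np.unique(groups))
        assert n_links == int(0.5 * 400 / 2)
        # linked mothers are full siblings: genotype correlation ~ 0.5
        gm = cohort.parent_genotypes["mother"].astype(float)
        pairs = [(a, np.flatnonzero(groups == g)[1])
                 for g in np.unique(groups[np.bincount(groups,
                                                       minlength=400) > 1])
                 for a in [np.flatnonzero(groups == g)[0]]]
        rs = [np.corrcoef(gm[a], gm[b])[0, 1] for a, b in pairs]
        assert np.mean(rs) == pytest.approx(0.5, abs=0.08)


class TestPhenotype:
    def test_unit_variance_and_exact_decomposition(self):
        cfg = sg.SimulationConfig(n_sibships=4000, n_variants=60, n_causal=30,
                                  beta_direct=0.07, eta_parental=0.05,
                                  eta_sibling=0.02, am_corr=0.2,
                                  strat={"freq_divergence": 0.05,
                                         "pheno_offset": 0.2},
                                  shared_env_var=0.1, seed=21)
        cohort = sg.simulate_cohort(cfg)
        y = cohort.phenotypes["trait"].to_numpy()
        assert np.var(y) == pytest.approx(1.0, abs=0.05)
        comp = cohort.truth["trait"]["components"]
        assert set(comp.columns) >= {"direct", "parental", "sibling",
                                     "stratification", "shared_env", "noise"}
        total = comp.sum(axis=1).to_numpy()
        assert np.var(total) == pytest.approx(np.var(y), rel=1e-9)

    def test_all_effects_off_gives_standard_normal_noise(self):
        cfg = sg.SimulationConfig(n_sibships=3000, n_variants=5, seed=2)
        cohort = sg.simulate_cohort(cfg)
        y = cohort.phenotypes["trait"].to_numpy()
        assert abs(y.mean()) < 0.05
        assert np.var(y) == pytest.approx(1.0, abs=0.05)

    def test_parental_effect_requires_parent_genotypes(self):
        cfg = sg.SimulationConfig(n_sibships=50, n_variants=5,
                                  eta_parental=0.1, seed=2)
        cohort = sg.simulate_sibships(sg.simulate_parent_pool(cfg))
        cohort.parent_genotypes = None
        with pytest.raises(ValueError, match="parental genotypes"):
            sg.simulate_phenotype(cohort, cfg)

    def test_missing_rate_applied(self):
        cfg = sg.SimulationConfig(n_sibships=2000, n_variants=5, seed=4)
        cohort = sg.simulate_cohort(cfg, missing_rate=0.2)
        frac = cohort.phenotypes["trait"].isna().mean()
        assert frac == pytest.approx(0.2, abs=0.03)


class TestLdscGenerator:
    @pytest.mark.parametrize("h2,a,n,m", [
        (0.0, 0.0, 10_000, 50_000),   # null: mean chi2 ~ 1
        (0.4, 0.0, 10_000, 50_000),   # polygenic signal only
        (0.0, 5e-4, 2_000, 30_000),   # pure confounding: mean chi2 ~ 2
    ])
    def test_mean_chi2_matches_closed_form(self, h2, a, n, m):
        cfg = LdscSimConfig(M=m, N=n, h2_true=h2, a_confound=a,
                            mean_ldscore=50.0, seed=8)
        df = simulate_ldsc_summary(cfg)
        lbar = df["L2"].mean()
        want = 1.0 + n * h2 * lbar / m + n * a
        assert df["CHI2"].mean() == pytest.approx(want, rel=0.05)

    def test_h2_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            LdscSimConfig(h2_true=1.2)

    def test_pair_cross_products_follow_model(self):
        c1 = LdscSimConfig(M=30_000, N=20_000, h2_true=0.4, seed=13)
        c2 = LdscSimConfig(M=30_000, N=20_000, h2_true=0.3, seed=13)
        a, b = sg.simulate_ldsc_pair(c1, c2, rg=0.5, cross_intercept=0.3)
        prod = (a["Z"] * b["Z"]).mean()
        want = (np.sqrt(c1.N * c2.N * c1.h2_true * c2.h2_true) * 0.5
                * a["L2"].mean() / c1.M + 0.3)
        assert prod == pytest.approx(want, rel=0.1)


class TestSds:
    def test_empty_table_gives_empty_sds(self):
        out = sg.simulate_sds(pd.DataFrame(columns=["SNP", "CHR", "BP"]), 1.0)
        assert out.empty

    def test_null_selection_uncorrelated(self):
        cfg = sg.SimulationConfig(n_sibships=10, n_variants=2000,
                                  n_causal=500, beta_direct=0.05, seed=6)
        pool = sg.simulate_parent_pool(cfg)
        sds = sg.simulate_sds(pool.variants, selection_strength=0.0, seed=6)
        beta = pool.variants["BETA_TRUE"].to_numpy()
        tsds = sds["SDS"].to_numpy() * np.where(beta < 0, -1, 1)
        from scipy.stats import spearmanr
        assert abs(spearmanr(tsds, np.abs(beta)).statistic) < 0.05
        causal = beta != 0
        assert abs(tsds[causal].mean()) < 3.5 / np.sqrt(causal.sum())

    def test_selection_creates_tsds_enrichment(self):
        cfg = sg.SimulationConfig(n_sibships=10, n_variants=2000,
                                  n_causal=500, beta_direct=0.05, seed=6)
        pool = sg.simulate_parent_pool(cfg)
        sds = sg.simulate_sds(pool.variants, selection_strength=1.0, seed=6)
        beta = pool.variants["BETA_TRUE"].to_numpy()
        causal = beta != 0
        tsds = sds["SDS"].to_numpy() * np.sign(np.where(beta == 0, 1, beta))
        assert tsds[causal].mean() > 3 * tsds[causal].std() / np.sqrt(
            causal.sum())
        assert sds["SELECTED"].sum() > 0


def test_same_seed_reproduces_cohort_exactly():
    cfg = sg.SimulationConfig(n_sibships=300, n_variants=50, beta_direct=0.1,
                              eta_parental=0.05, am_corr=0.3,
                              shared_env_var=0.1, seed=77)
    a = sg.simulate_cohort(cfg)
    b = sg.simulate_cohort(cfg)
    assert np.array_equal(a.genotypes, b.genotypes)
    assert np.allclose(a.phenotypes["trait"], b.phenotypes["trait"])


def test_cohort_tsv_round_trip(tmp_path):
    cfg = sg.SimulationConfig(n_sibships=50, n_variants=10, n_pcs=3, seed=1)
    cohort = sg.simulate_cohort(cfg)
    cohort.write(tmp_path / "c")
    back = sg.SibshipCohort.read(tmp_path / "c")
    assert np.array_equal(back.genotypes, cohort.genotypes)
    assert list(back.phenotypes.columns) == ["trait"]
    assert np.allclose(back.phenotypes["trait"], cohort.phenotypes["trait"])
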