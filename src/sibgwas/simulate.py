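"""Family-cohort and summary-statistic simulators.

The generator reproduces the confounding structures that within-sibship
association models are designed to remove:

* **assortative mating** — mates are rank-matched on phenotype plus calibrated
  matching noise so the cross-mate phenotypic correlation hits a target;
* **population stratification** — two subpopulations with diverged allele
  frequencies and a phenotype mean offset, with simulated principal components
  that tag the structure only up to a configurable leakage noise;
* **indirect genetic effects** — parental and sibling genotypes act on the
  index individual's phenotype over and above the direct allelic effect;
* **cryptic relatedness** — a configurable fraction of sibships are linked
  through a shared parent-generation founder couple (their mothers are full
  siblings) and share their common-environment draw.

Children are produced by Mendelian transmission: each allele is drawn
independently and uniformly from the parent's two alleles. All randomness
derives from ``config.seed`` via named SeedSequence substreams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import LdscSimConfig, SimulationConfig
from .cohort import SibshipCohort, variant_id

_SUBSTREAMS = ("variants", "parents", "matching", "cryptic", "children",
               "covariates", "phenotype", "ldsc", "sds")


def _rngs(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(_SUBSTREAMS, children)}


def _make_variant_table(config: SimulationConfig, rng) -> pd.DataFrame:
    m = config.n_variants
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)
    sign = rng.choice([-1.0, 1.0], size=m)
    dp = 0.5 * config.strat.freq_divergence * sign
    p0 = np.clip(maf + dp, 0.005, 0.995)
    p1 = np.clip(maf - dp, 0.005, 0.995)
    # spread variants over 22 chromosomes with increasing positions
    chrom = 1 + (np.arange(m) * 22) // m
    bp = np.empty(m, dtype=np.int64)
    for c in np.unique(chrom):
        k = int((chrom == c).sum())
        bp[chrom == c] = 1_000_000 + 50_000 * np.arange(k)
    causal = np.zeros(m, dtype=bool)
    causal[rng.choice(m, size=config.n_causal_effective, replace=False)] = True
    beta_true = np.where(causal, config.beta_direct, 0.0)
    pooled = 0.5 * (p0 + p1)
    return pd.DataFrame({
        "SNP": [variant_id(c, b) for c, b in zip(chrom, bp)],
        "CHR": chrom, "BP": bp, "EA": "A", "OA": "G",
        "MAF": np.minimum(pooled, 1 - pooled), "INFO": 1.0,
        "P0": p0, "P1": p1, "EAF_TRUE": pooled,
        "CAUSAL": causal, "BETA_TRUE": beta_true,
    })


@dataclass
class ParentPool:
    """Mate-paired parental generation: row i is the couple founding sibship i."""

    father_genotypes: np.ndarray
    mother_genotypes: np.ndarray
    father_phenotype: np.ndarray
    mother_phenotype: np.ndarray
    subpop: np.ndarray
    variants: pd.DataFrame
    config: SimulationConfig

    @property
    def n_couples(self) -> int:
        return len(self.subpop)

    def mate_phenotype_correlation(self) -> float:
        return float(np.corrcoef(self.father_phenotype, self.mother_phenotype)[0, 1])


def _parent_phenotype(genotypes, variants, subpop, config, rng):
    beta = variants["BETA_TRUE"].to_numpy()
    y = genotypes @ beta + config.strat.pheno_offset * subpop
    p = variants["EAF_TRUE"].to_numpy()
    var_g = float(np.sum(beta**2 * 2 * p * (1 - p)))
    var_strat = config.strat.pheno_offset**2 * 0.25
    noise_var = max(1.0 - var_g - var_strat, 0.0)
    return y + rng.normal(0.0, np.sqrt(noise_var), size=len(y))


def _assortative_pairing(phen_f, phen_m, am_corr, rng):
    """Return an index into mothers pairing each father to a mate.

    Mothers are rank-matched against father phenotype plus matching noise with
    variance var(phen) * (1/r^2 - 1), which yields a cross-mate phenotypic
    correlation of approximately ``am_corr`` for unit-variance phenotypes.
    """
    n = len(phen_f)
    if am_corr == 0:
        return rng.permutation(n)
    sd_noise = np.std(phen_f) * np.sqrt(1.0 / am_corr**2 - 1.0)
    noisy = phen_f + rng.normal(0.0, sd_noise, size=n)
    order_f = np.argsort(noisy)
    order_m = np.argsort(phen_m)
    pairing = np.empty(n, dtype=np.int64)
    pairing[order_f] = order_m
    return pairing


def simulate_parent_pool(config: SimulationConfig,
                         variants: pd.DataFrame | None = None) -> ParentPool:
    """Simulate 2 x n_sibships parents paired into couples within subpopulation.

    Pass a pre-built ``variants`` table to share one variant panel (and true
    effects) across several simulated study cohorts.
    """
    config.validate()
    rngs = _rngs(config.seed)
    if variants is None:
        variants = _make_variant_table(config, rngs["variants"])
    n = config.n_sibships
    subpop = (np.arange(n) % 2).astype(np.int8)  # balanced two-subpopulation design
    p_by_pop = np.vstack([variants["P0"].to_numpy(), variants["P1"].to_numpy()])
    rng_p = rngs["parents"]
    gf = rng_p.binomial(2, p_by_pop[subpop]).astype(np.int8)
    gm = rng_p.binomial(2, p_by_pop[subpop]).astype(np.int8)
    yf = _parent_phenotype(gf, variants, subpop, config, rng_p)
    ym = _parent_phenotype(gm, variants, subpop, config, rng_p)
    # pair mates within subpopulation so children inherit a well-defined label
    pairing = np.arange(n)
    for pop in (0, 1):
        idx = np.flatnonzero(subpop == pop)
        if len(idx) < 2:
            continue
        local = _assortative_pairing(yf[idx], ym[idx], config.am_corr,
                                     rngs["matching"])
        pairing[idx] = idx[local]
    return ParentPool(
        father_genotypes=gf, mother_genotypes=gm[pairing],
        father_phenotype=yf, mother_phenotype=ym[pairing],
        subpop=subpop, variants=variants, config=config,
    )


def _mendelian_children(gf, gm, rng):
    """One allele drawn from each parent; parent genotype g transmits alt w.p. g/2."""
    return (rng.binomial(1, gf / 2.0) + rng.binomial(1, gm / 2.0)).astype(np.int8)


def simulate_sibships(parents: ParentPool, config: SimulationConfig | None = None
                      ) -> SibshipCohort:
    """Draw sibships from the mate pairs by Mendelian transmission."""
    config = parents.config if config is None else config
    rngs = _rngs(config.seed)
    n_fam = parents.n_couples
    gf = parents.father_genotypes.copy()
    gm = parents.mother_genotypes.copy()
    variants = parents.variants
    p_by_pop = np.vstack([variants["P0"].to_numpy(), variants["P1"].to_numpy()])

    # cryptic relatedness: linked sibship pairs whose mothers are full siblings
    founder_group = np.arange(n_fam)
    n_links = int(config.cryptic_relatedness_frac * n_fam / 2)
    if n_links:
        rng_c = rngs["cryptic"]
        chosen = rng_c.choice(n_fam, size=2 * n_links, replace=False)
        for a, b in chosen.reshape(-1, 2):
            p = p_by_pop[parents.subpop[a]]
            grand_f = rng_c.binomial(2, p).astype(np.int8)
            grand_m = rng_c.binomial(2, p).astype(np.int8)
            gm[a] = _mendelian_children(grand_f, grand_m, rng_c)
            gm[b] = _mendelian_children(grand_f, grand_m, rng_c)
            founder_group[b] = founder_group[a]

    rng_k = rngs["children"]
    if isinstance(config.sibs_per_family, int):
        sizes = np.full(n_fam, config.sibs_per_family, dtype=np.int64)
    else:
        keys = np.array([int(k) for k in config.sibs_per_family])
        probs = np.array([float(v) for v in config.sibs_per_family.values()])
        sizes = rng_k.choice(keys, size=n_fam, p=probs / probs.sum())
    fam_index = np.repeat(np.arange(n_fam), sizes)
    genotypes = _mendelian_children(gf[fam_index], gm[fam_index], rng_k)

    rng_cov = rngs["covariates"]
    n_ind = len(fam_index)
    subpop = parents.subpop[fam_index]
    samples = pd.DataFrame({
        "IID": [f"F{f}_{j}" for f, j in
                zip(fam_index, np.concatenate([np.arange(s) for s in sizes]))],
        "FID": [f"F{f}" for f in fam_index],
        "father": [f"F{f}_dad" for f in fam_index],
        "mother": [f"F{f}_mum" for f in fam_index],
        "subpop": subpop,
        "sex": rng_cov.integers(0, 2, size=n_ind),
        "age": rng_cov.normal(50.0, 10.0, size=n_ind),
    })
    if config.pcs_from_genotypes:
        std = genotypes - genotypes.mean(axis=0)
        sd = std.std(axis=0)
        sd[sd == 0] = 1.0
        u, s, _ = np.linalg.svd(std / sd, full_matrices=False)
        pcs = u[:, :config.n_pcs] * s[:config.n_pcs]
    else:
        pcs = rng_cov.normal(0.0, 1.0, size=(n_ind, config.n_pcs))
        if config.n_pcs:
            pcs[:, 0] = (subpop - subpop.mean()) + rng_cov.normal(
                0.0, config.strat.pc_leakage_sd, size=n_ind)
    for k in range(pcs.shape[1]):
        samples[f"PC{k + 1}"] = pcs[:, k]

    return SibshipCohort(
        genotypes=genotypes, samples=samples, variants=variants,
        parent_genotypes={"father": gf, "mother": gm,
                          "fam_index": fam_index,
                          "founder_group": founder_group},
        truth={"config": config, "sizes": sizes},
    )


def simulate_phenotype(cohort: SibshipCohort, config: SimulationConfig,
                       name: str = "trait", missing_rate: float = 0.0,
                       seed_offset: int = 0) -> SibshipCohort:
    """Attach a phenotype built from direct, indirect and environmental parts.

    Residual noise variance is set to top the systematic variance up to 1, so
    coefficients stay on the phenotype-SD scale without rescaling. The realized
    component vectors are stored in ``cohort.truth[name]`` so variance can be
    decomposed exactly (including covariances between components).
    """
    rng = _rngs(config.seed + seed_offset)["phenotype"]
    if config.eta_parental != 0 and cohort.parent_genotypes is None:
        raise ValueError("parental genotypes required when eta_parental != 0")
    causal = cohort.variants["CAUSAL"].to_numpy().astype(float)
    beta = causal * config.beta_direct
    g = cohort.genotypes
    parts = {"direct": g @ beta}

    pg = cohort.parent_genotypes
    fam_index = pg["fam_index"] if pg else None
    if config.eta_parental != 0:
        mid = (pg["father"] + pg["mother"]).astype(np.float64) @ causal
        parts["parental"] = config.eta_parental * mid[fam_index]
    if config.eta_sibling != 0:
        score = g @ causal
        fam_sum = pd.Series(score).groupby(cohort.sibship_ids).transform("sum")
        parts["sibling"] = config.eta_sibling * (fam_sum.to_numpy() - score)
    if config.strat.pheno_offset:
        parts["stratification"] = (config.strat.pheno_offset
                                   * cohort.samples["subpop"].to_numpy())
    if config.shared_env_var > 0:
        groups = (pg["founder_group"] if pg is not None
                  else np.arange(cohort.samples["FID"].nunique()))
        env = rng.normal(0.0, np.sqrt(config.shared_env_var), size=len(groups))
        codes = pd.factorize(cohort.samples["FID"])[0]
        parts["shared_env"] = env[groups[codes]] if pg is not None else env[codes]

    systematic = sum(parts.values()) if parts else np.zeros(cohort.n_individuals)
    var_sys = float(np.var(systematic))
    noise_var = max(1.0 - var_sys, 0.0)
    parts["noise"] = rng.normal(0.0, np.sqrt(noise_var), size=cohort.n_individuals)
    y = systematic + parts["noise"]
    if missing_rate > 0:
        y = np.where(rng.random(len(y)) < missing_rate, np.nan, y)
    cohort.phenotypes[name] = y
    cohort.truth[name] = {
        "components": pd.DataFrame(parts),
        "variance_systematic": var_sys,
        "variance_noise": noise_var,
        "beta_true": beta,
    }
    return cohort


def simulate_cohort(config: SimulationConfig, phenotype: str = "trait",
                    missing_rate: float = 0.0,
                    variants: pd.DataFrame | None = None) -> SibshipCohort:
    """Convenience: parent pool -> sibships -> one phenotype."""
    pool = simulate_parent_pool(config, variants=variants)
    cohort = simulate_sibships(pool)
    return simulate_phenotype(cohort, config, name=phenotype,
                              missing_rate=missing_rate)


# --------------------------------------------------------------------- LDSC
def simulate_ldsc_summary(config: LdscSimConfig) -> pd.DataFrame:
    """GWAS Z scores drawn directly under chi2 ~ N h2 l_j / M + N a + 1."""
    config.validate()
    rng = _rngs(config.seed)["ldsc"]
    df = _ldsc_frame(config.M, config.mean_ldscore, rng)
    var = 1.0 + config.N * config.a_confound \
        + config.N * config.h2_true * df["L2"].to_numpy() / config.M
    df["Z"] = rng.normal(size=config.M) * np.sqrt(var)
    df["CHI2"] = df["Z"] ** 2
    df["N"] = config.N
    return df


def simulate_ldsc_pair(config1: LdscSimConfig, config2: LdscSimConfig,
                       rg: float, cross_intercept: float = 0.0,
                       seed: int | None = None,
                       frame: pd.DataFrame | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two traits' Z scores with genetic correlation ``rg`` on a shared panel.

    E[z1 z2] = sqrt(N1 N2) * rg * sqrt(h2_1 h2_2) * l_j / M + cross_intercept,
    the cross-trait LD score regression model with a sample-overlap intercept.
    """
    if not (-1 <= rg <= 1):
        raise ValueError("rg must be in [-1, 1]")
    rng = _rngs(config1.seed if seed is None else seed)["ldsc"]
    m = config1.M
    if config2.M != m:
        raise ValueError("both traits must share the variant panel")
    if frame is not None:
        if len(frame) != m:
            raise ValueError("supplied frame must match M")
        df = frame[["SNP", "CHR", "BP", "L2"]].copy()
    else:
        df = _ldsc_frame(m, config1.mean_ldscore, rng)
    l2 = df["L2"].to_numpy()

    def _draw_corr(rho):
        a = rng.normal(size=m)
        b = rho * a + np.sqrt(max(1 - rho**2, 0.0)) * rng.normal(size=m)
        return a, b

    g1, g2 = _draw_corr(rg)
    s1 = np.sqrt(config1.N * config1.h2_true * l2 / m)
    s2 = np.sqrt(config2.N * config2.h2_true * l2 / m)
    e_var1 = 1.0 + config1.N * config1.a_confound
    e_var2 = 1.0 + config2.N * config2.a_confound
    rho_e = cross_intercept / np.sqrt(e_var1 * e_var2)
    if abs(rho_e) > 1:
        raise ValueError("cross_intercept implies |noise correlation| > 1")
    e1, e2 = _draw_corr(rho_e)
    out = []
    for cfg, s, g, e, ev in ((config1, s1, g1, e1, e_var1),
                             (config2, s2, g2, e2, e_var2)):
        d = df.copy()
        d["Z"] = s * g + np.sqrt(ev) * e
        d["CHI2"] = d["Z"] ** 2
        d["N"] = cfg.N
        out.append(d)
    return out[0], out[1]


def _ldsc_frame(m, mean_ldscore, rng):
    l2 = 1.0 + rng.exponential(mean_ldscore - 1.0, size=m)
    chrom = 1 + (np.arange(m) * 22) // m
    bp = np.empty(m, dtype=np.int64)
    for c in np.unique(chrom):
        k = int((chrom == c).sum())
        bp[chrom == c] = 1_000_000 + 10_000 * np.arange(k)
    return pd.DataFrame({
        "SNP": [variant_id(c, b) for c, b in zip(chrom, bp)],
        "CHR": chrom, "BP": bp, "L2": l2,
    })


# ---------------------------------------------------------------------- SDS
def simulate_sds(variants: pd.DataFrame, selection_strength: float = 0.0,
                 seed: int = 0) -> pd.DataFrame:
    """Synthetic singleton-density scores for a variant table.

    Raw SDS are standard normal within frequency strata. With positive
    ``selection_strength`` the derived (effect) allele of causal variants is
    pushed in the direction that makes it look recently selected when it
    increases the trait, so tSDS becomes positively correlated with the true
    effect rank. This stands in for precomputed reference SDS tables, which
    are out of scope here.
    """
    rng = _rngs(seed)["sds"]
    cols = ["SNP", "CHR", "BP", "DA", "AA", "DAF", "SDS", "SELECTED"]
    if len(variants) == 0:
        return pd.DataFrame(columns=cols)
    m = len(variants)
    daf = variants["EAF_TRUE"].to_numpy() if "EAF_TRUE" in variants else \
        rng.uniform(0.05, 0.95, size=m)
    sds = rng.normal(size=m)
    selected = np.zeros(m, dtype=bool)
    if selection_strength > 0 and "BETA_TRUE" in variants:
        beta = variants["BETA_TRUE"].to_numpy()
        mag = np.abs(beta)
        if mag.max() > 0:
            rank = pd.Series(mag).rank(method="average").to_numpy() / m
            shift = selection_strength * rank * np.sign(beta)
            sds = sds + shift
            selected = mag >= np.quantile(mag[mag > 0], 0.9)
    return pd.DataFrame({
        "SNP": variants["SNP"].to_numpy(),
        "CHR": variants["CHR"].to_numpy(),
        "BP": variants["BP"].to_numpy(),
        "DA": variants["EA"].to_numpy() if "EA" in variants else "A",
        "AA": variants["OA"].to_numpy() if "OA" in variants else "G",
        "DAF": daf, "SDS": sds, "SELECTED": selected,
    })
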