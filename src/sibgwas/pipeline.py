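"""End-to-end desk-scale scenarios.

A scenario simulates an independent discovery cohort plus several study
cohorts sharing one variant panel, runs population and within-sibship GWAS per
study, meta-analyses them, and then exercises the downstream inference chain:
shrinkage of the weighted scores, LD-score-regression heritability and genetic
correlation comparisons (on summary statistics generated directly under the
LDSC model), within-sibship Mendelian randomization, and the tSDS polygenic
adaptation test. Every stage writes tab-separated intermediates and the report
is reproducible byte-for-byte from a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adaptation as adapt
from . import ldsc as ldsc_mod
from .config import LdscSimConfig, SimulationConfig
from .gwas import PopulationGwas, WithinSibshipGwas, qc_filter_variants
from .meta import fixed_effects_meta, standardize_units, study_effective_n
from .mr import IvwMr, mr_difference_jackknife
from .shrinkage import (ShrinkageModel, select_instruments,
                        study_level_heterogeneity)
from .simulate import (_make_variant_table, _rngs, simulate_cohort,
                       simulate_ldsc_pair, simulate_phenotype,
                       simulate_sds)

log = logging.getLogger(__name__)

TABLE_NAMES = ("shrinkage", "h2", "rg", "mr", "adaptation")


DEFAULT_SCENARIO = {
    "name": "education_like",
    "seed": 0,
    "cohort": {
        "sibs_per_family": 2, "n_variants": 400, "n_causal": 60,
        "maf_range": [0.1, 0.5], "beta_direct": 0.08, "eta_parental": 0.06,
        "eta_sibling": 0.0, "am_corr": 0.2,
        "strat": {"freq_divergence": 0.05, "pheno_offset": 0.1},
        "shared_env_var": 0.1, "cryptic_relatedness_frac": 0.0,
    },
    "studies": [4000, 2500],
    "discovery_n_sibships": 12000,
    "shrinkage": {"p_threshold": 1e-5},
    "ldsc": {"M": 12000, "N": 30000, "h2": 0.3, "a": 0.0,
             "shrinkage_k": 0.3, "cross_intercept": 0.4, "mean_ldscore": 40},
    "rg": {"h2_other": 0.25, "rg_pop": 0.6, "rg_ws": 0.25, "N": 30000},
    "mr": {"causal_effect": 0.2, "eta_parental_outcome": 0.06,
           "n_sibships": 6000, "p_threshold": 5e-8},
    "adaptation": {"selection_strength": 1.0},
}


@dataclass
class ScenarioReport:
    name: str
    seed: int
    shrinkage: pd.DataFrame = None
    h2: pd.DataFrame = None
    rg: pd.DataFrame = None
    mr: pd.DataFrame = None
    adaptation: pd.DataFrame = None
    intermediates: dict = field(default_factory=dict, repr=False)

    def tables(self):
        return {name: getattr(self, name) for name in TABLE_NAMES}

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "scenario.json", "w") as fh:
            json.dump({"name": self.name, "seed": self.seed}, fh)
        for name, table in self.tables().items():
            if table is not None:
                table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        for name, table in self.intermediates.items():
            table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        with open(out / "report.txt", "w") as fh:
            fh.write(make_report(self))

    @classmethod
    def load(cls, out_dir) -> "ScenarioReport":
        out = Path(out_dir)
        with open(out / "scenario.json") as fh:
            meta = json.load(fh)
        kwargs = {}
        for name in TABLE_NAMES:
            path = out / f"{name}.tsv"
            if path.exists():
                kwargs[name] = pd.read_csv(path, sep="\t")
        return cls(name=meta["name"], seed=meta["seed"], **kwargs)


def _seeds(seed: int, k: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(k, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def _study_gwas(cohort, phenotype: str, label: str):
    """Fit both models on identical samples and standardize units."""
    sd_pheno = float(np.nanstd(cohort.phenotypes[phenotype]))
    results = {}
    for cls in (PopulationGwas, WithinSibshipGwas):
        model = cls(cohort, phenotype)
        res = model.fit()
        table = qc_filter_variants(standardize_units(res.table, sd_pheno))
        table["STUDY"] = label
        results[cls.model_tag] = (table, res.sd_resid / sd_pheno)
    return results


def run_scenario(config: dict | str | Path, out_dir=None) -> ScenarioReport:
    """Run one scenario end to end. ``config`` is a dict or a YAML path."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULT_SCENARIO, **config}
    for key in ("cohort", "shrinkage", "ldsc", "rg", "mr", "adaptation"):
        cfg[key] = {**DEFAULT_SCENARIO[key], **(config.get(key) or {})}
    seed = int(cfg["seed"])
    seeds = _seeds(seed, 10 + len(cfg["studies"]))
    report = ScenarioReport(name=cfg["name"], seed=seed)

    # shared variant panel across discovery and study cohorts
    base = SimulationConfig(n_sibships=10, seed=seeds[0], **cfg["cohort"])
    variants = _make_variant_table(base, _rngs(seeds[0])["variants"])

    log.info("stage discovery: %d sibships", cfg["discovery_n_sibships"])
    disc_cfg = dataclasses.replace(base, n_sibships=cfg["discovery_n_sibships"],
                                   seed=seeds[1])
    disc_cohort = simulate_cohort(disc_cfg, variants=variants)
    disc_table = PopulationGwas(disc_cohort, "trait").fit().table
    disc_table = qc_filter_variants(disc_table)
    report.intermediates["discovery_population"] = disc_table

    study_tables = {"population": [], "within_sibship": []}
    study_resid = {"population": [], "within_sibship": []}
    for i, n_sib in enumerate(cfg["studies"]):
        log.info("stage study %d: %d sibships", i, n_sib)
        scfg = dataclasses.replace(base, n_sibships=int(n_sib),
                                   seed=seeds[2 + i])
        cohort = simulate_cohort(scfg, variants=variants)
        for tag, (table, sd_resid) in _study_gwas(cohort, "trait",
                                                  f"study{i}").items():
            table["EFF_N"] = (1.0 / table["SE"] ** 2) * sd_resid**2 / (
                2 * table["EAF"] * (1 - table["EAF"]))
            study_tables[tag].append(table)
            study_resid[tag].append(sd_resid)
            report.intermediates[f"study{i}_{tag}"] = table

    meta_tables = {tag: fixed_effects_meta(tabs)
                   for tag, tabs in study_tables.items()}
    for tag, table in meta_tables.items():
        table["MODEL"] = tag
        report.intermediates[f"meta_{tag}"] = table
        log.info("stage meta (%s): %d variants", tag, len(table))

    # ---- shrinkage of weighted scores ------------------------------------
    shr = cfg["shrinkage"]
    instruments = select_instruments(disc_table,
                                     p_threshold=float(shr["p_threshold"]),
                                     source="discovery")
    rows = []
    if len(instruments) >= 2:
        model = ShrinkageModel.from_tables(meta_tables["population"],
                                           meta_tables["within_sibship"],
                                           instruments, target="meta")
        res = model.fit()
        lo, hi = res.ci
        study_deltas, study_ses = [], []
        for pop_t, ws_t in zip(study_tables["population"],
                               study_tables["within_sibship"]):
            sm = ShrinkageModel.from_tables(pop_t, ws_t, instruments,
                                            target=None)
            if sm.M >= 2:
                sres = sm.fit()
                study_deltas.append(sres.delta)
                study_ses.append(sres.se)
        het_q = het_p = np.nan
        if len(study_deltas) >= 2:
            het_q, _, het_p = study_level_heterogeneity(study_deltas,
                                                        study_ses)
        rows.append({
            "phenotype": "trait", "threshold": shr["p_threshold"],
            "M": res.M, "delta_pct": res.percent, "se_pct": 100 * res.se,
            "ci_low_pct": 100 * lo, "ci_high_pct": 100 * hi, "p": res.p,
            "Q": res.Q, "Q_df": res.Q_df, "Q_p": res.Q_p,
            "study_het_Q": het_q, "study_het_p": het_p,
        })
    else:
        log.warning("shrinkage skipped: fewer than 2 instruments")
    report.shrinkage = pd.DataFrame(rows)

    # ---- LDSC h2 comparison (summary stats under the generative model) ---
    lc = cfg["ldsc"]
    k = float(lc["shrinkage_k"])
    pop_cfg = LdscSimConfig(M=int(lc["M"]), N=float(lc["N"]),
                            h2_true=float(lc["h2"]),
                            a_confound=float(lc["a"]),
                            mean_ldscore=float(lc["mean_ldscore"]),
                            seed=seeds[6])
    ws_cfg = dataclasses.replace(pop_cfg,
                                 h2_true=(1 - k) ** 2 * float(lc["h2"]))
    pop_sum, ws_sum = simulate_ldsc_pair(pop_cfg, ws_cfg, rg=1.0,
                                         cross_intercept=float(
                                             lc["cross_intercept"]),
                                         seed=seeds[6])
    fit_pop = ldsc_mod.LdscModel.from_table(pop_sum, n=pop_cfg.N).fit()
    fit_ws = ldsc_mod.LdscModel.from_table(ws_sum, n=ws_cfg.N).fit()
    cross = ldsc_mod.CrossTraitLdsc(pop_sum["Z"], ws_sum["Z"],
                                    pop_sum["L2"], pop_cfg.N, ws_cfg.N).fit()
    diff = ldsc_mod.h2_difference_test(fit_pop, fit_ws,
                                       np.clip(cross.cross_intercept,
                                               -0.99, 0.99))
    report.h2 = pd.DataFrame([
        {"model": "population", "h2": fit_pop.h2, "se": fit_pop.h2_se,
         "intercept": fit_pop.intercept, "mean_chi2": fit_pop.mean_chi2,
         "ratio": fit_pop.ratio, "p": np.nan},
        {"model": "within_sibship", "h2": fit_ws.h2, "se": fit_ws.h2_se,
         "intercept": fit_ws.intercept, "mean_chi2": fit_ws.mean_chi2,
         "ratio": fit_ws.ratio, "p": np.nan},
        {"model": "expected_ws", "h2": ldsc_mod.expected_ws_h2(fit_pop.h2, k),
         "se": np.nan, "intercept": np.nan, "mean_chi2": np.nan,
         "ratio": np.nan, "p": np.nan},
        {"model": "difference", "h2": diff.diff, "se": diff.se,
         "intercept": np.nan, "mean_chi2": np.nan, "ratio": np.nan,
         "p": diff.p},
    ])

    # ---- rg comparison ----------------------------------------------------
    rc = cfg["rg"]
    other_pop = dataclasses.replace(pop_cfg, h2_true=float(rc["h2_other"]),
                                    N=float(rc["N"]))
    other_ws = dataclasses.replace(ws_cfg, h2_true=float(rc["h2_other"]),
                                   N=float(rc["N"]))
    frame = pop_sum[["SNP", "CHR", "BP", "L2"]]
    pop_a, pop_b = simulate_ldsc_pair(pop_cfg, other_pop,
                                      rg=float(rc["rg_pop"]), seed=seeds[7],
                                      frame=frame)
    ws_a, ws_b = simulate_ldsc_pair(ws_cfg, other_ws, rg=float(rc["rg_ws"]),
                                    seed=seeds[8], frame=frame)
    rg_pop = ldsc_mod.CrossTraitLdsc(pop_a["Z"], pop_b["Z"], frame["L2"],
                                     pop_cfg.N, other_pop.N).fit()
    rg_ws = ldsc_mod.CrossTraitLdsc(ws_a["Z"], ws_b["Z"], frame["L2"],
                                    ws_cfg.N, other_ws.N).fit()
    rg_diff = ldsc_mod.rg_difference_jackknife(
        (pop_a["Z"], pop_b["Z"], pop_cfg.N, other_pop.N),
        (ws_a["Z"], ws_b["Z"], ws_cfg.N, other_ws.N), frame["L2"])
    report.rg = pd.DataFrame([
        {"model": "population", "rg": rg_pop.rg, "se": rg_pop.se,
         "p": rg_pop.p},
        {"model": "within_sibship", "rg": rg_ws.rg, "se": rg_ws.se,
         "p": rg_ws.p},
        {"model": "difference", "rg": rg_diff.diff, "se": rg_diff.se,
         "p": rg_diff.p},
    ])

    # ---- MR ----------------------------------------------------------------
    mc = cfg["mr"]
    mr_cfg = dataclasses.replace(base, n_sibships=int(mc["n_sibships"]),
                                 seed=seeds[9])
    mr_cohort = simulate_cohort(mr_cfg, phenotype="exposure",
                                variants=variants)
    theta = float(mc["causal_effect"])
    eta_out = float(mc["eta_parental_outcome"])
    out_cfg = dataclasses.replace(mr_cfg, beta_direct=0.0,
                                  eta_parental=eta_out, am_corr=0.0,
                                  shared_env_var=0.0)
    mr_cohort = simulate_phenotype(mr_cohort, out_cfg, name="outcome",
                                   seed_offset=7)
    exp_vals = mr_cohort.phenotypes["exposure"].to_numpy()
    mr_cohort.phenotypes["outcome"] = (
        mr_cohort.phenotypes["outcome"].to_numpy() + theta * exp_vals)
    mr_instruments = select_instruments(disc_table,
                                        p_threshold=float(mc["p_threshold"]),
                                        source="discovery")
    mr_rows = []
    if len(mr_instruments) >= 2:
        gw = {}
        for pheno in ("exposure", "outcome"):
            gw[pheno] = {tag: t for tag, (t, _) in
                         _study_gwas(mr_cohort, pheno, "mr").items()}
        mr_res = {}
        for tag in ("population", "within_sibship"):
            mr_res[tag] = IvwMr.from_tables(gw["exposure"][tag],
                                            gw["outcome"][tag],
                                            mr_instruments, model=tag).fit()
        snps = [s for s in mr_instruments.snps
                if s in set(gw["exposure"]["population"]["SNP"])]
        args = []
        for tag in ("population", "within_sibship"):
            e = gw["exposure"][tag].set_index("SNP").loc[snps]
            o = gw["outcome"][tag].set_index("SNP").loc[snps]
            args += [e["BETA"].to_numpy(), o["BETA"].to_numpy(),
                     o["SE"].to_numpy()]
        mr_diff = mr_difference_jackknife(*args)
        for tag, res in mr_res.items():
            lo, hi = res.ci
            mr_rows.append({"model": tag, "beta": res.beta, "se": res.se,
                            "ci_low": lo, "ci_high": hi, "p": res.p,
                            "n_instruments": res.n_instruments})
        mr_rows.append({"model": "difference", "beta": mr_diff.diff,
                        "se": mr_diff.se, "ci_low": np.nan, "ci_high": np.nan,
                        "p": mr_diff.p, "n_instruments": mr_diff.n_instruments})
    else:
        log.warning("MR skipped: fewer than 2 instruments")
    report.mr = pd.DataFrame(mr_rows)

    # ---- polygenic adaptation ---------------------------------------------
    ac = cfg["adaptation"]
    sds = simulate_sds(variants, float(ac["selection_strength"]),
                       seed=seeds[5])
    sds = adapt.normalize_sds(adapt.exclude_selected_regions(sds))
    adapt_rows = []
    for tag, table in meta_tables.items():
        merged = adapt.align_tsds(sds, table)
        merged = adapt.filter_low_effective_n(merged)
        res = adapt.tsds_correlation(merged["TSDS"], merged["ABS_Z"],
                                     merged["CHR"], merged["BP"], model=tag)
        adapt_rows.append({"model": tag, "rho": res.rho, "se": res.se,
                           "p": res.p, "n_variants": res.n_variants})
    report.adaptation = pd.DataFrame(adapt_rows)

    if out_dir is not None:
        report.write(out_dir)
    return report


def make_report(report: ScenarioReport) -> str:
    """Render the scenario's result tables as a plain-text summary."""
    lines = [f"scenario: {report.name} (seed {report.seed})", ""]
    titles = {
        "shrinkage": "Shrinkage of weighted scores (population -> within-sibship)",
        "h2": "LDSC SNP heritability comparison",
        "rg": "Cross-trait genetic correlation comparison",
        "mr": "IVW Mendelian randomization comparison",
        "adaptation": "tSDS polygenic adaptation test",
    }
    for name, table in report.tables().items():
        lines.append(f"## {titles[name]}")
        if table is None or table.empty:
            lines.append("(not run)")
        else:
            lines.append(table.round(6).to_string(index=False))
        lines.append("")
    return "\n".join(lines)
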