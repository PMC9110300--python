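"""Unit standardisation, effective sample size and fixed-effects meta-analysis.

Per-study association tables are put on the phenotype-SD scale by dividing
betas and SEs by the cohort phenotype SD (Z scores are scale-invariant), then
combined by inverse-variance-weighted fixed-effects meta-analysis after allele
harmonisation. The effective sample size implied by a GWAS standard error is

    effective N = (1 / se^2) * sd_resid^2 / (2 * MAF * (1 - MAF))

which is the analytic OLS identity inverted for N; clustering and within-family
centering reduce it below the raw N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def standardize_units(table: pd.DataFrame, phenotype_sd: float) -> pd.DataFrame:
    """Divide BETA and SE by the phenotype SD; Z scores are unchanged."""
    if phenotype_sd <= 0:
        raise ValueError("phenotype_sd must be positive")
    out = table.copy()
    out["BETA"] = out["BETA"] / phenotype_sd
    out["SE"] = out["SE"] / phenotype_sd
    for col in ("FBETA", "FSE"):
        if col in out.columns:
            out[col] = out[col] / phenotype_sd
    return out


def effective_sample_size(se, maf, sd_resid=1.0):
    """Independent observations implied by a GWAS SE at a given MAF."""
    se = np.asarray(se, dtype=float)
    maf = np.asarray(maf, dtype=float)
    maf = np.minimum(maf, 1.0 - maf)   # fold to minor allele
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if np.any((maf <= 0) | (maf >= 1)):
        raise ValueError("MAF must lie strictly inside (0, 1)")
    if np.any(np.asarray(sd_resid) <= 0):
        raise ValueError("sd_resid must be positive")
    out = (1.0 / se**2) * np.asarray(sd_resid) ** 2 / (2.0 * maf * (1.0 - maf))
    return float(out) if out.ndim == 0 else out


def study_effective_n(table: pd.DataFrame, sd_resid: float = 1.0,
                      maf_window=(0.1, 0.4)) -> float:
    """Study-level effective N: median per-variant value over mid-MAF variants.

    Low-frequency variants make the per-variant values noisy, so the summary
    is restricted to MAF in [0.1, 0.4].
    """
    maf = np.minimum(table["EAF"], 1 - table["EAF"])
    sel = table.loc[(maf >= maf_window[0]) & (maf <= maf_window[1])]
    sel = sel.loc[sel["SE"].notna()]
    if sel.empty:
        raise ValueError("no variants in the MAF window")
    vals = effective_sample_size(sel["SE"].to_numpy(),
                                 np.minimum(sel["EAF"], 1 - sel["EAF"]).to_numpy(),
                                 sd_resid)
    return float(np.median(vals))


@dataclass
class StudySummary:
    """One study's standardized association table plus its residual SD."""

    study: str
    phenotype: str
    sd_resid: float
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if self.sd_resid <= 0:
            raise ValueError("sd_resid must be positive")


def _harmonize(ref: pd.DataFrame, other: pd.DataFrame,
               drop_ambiguous: bool = False) -> pd.DataFrame:
    """Align ``other`` to the reference effect allele (swap + sign flip)."""
    merged = other.merge(ref[["SNP", "EA", "OA"]], on="SNP",
                         suffixes=("", "_ref"), how="inner")
    same = (merged["EA"] == merged["EA_ref"]) & (merged["OA"] == merged["OA_ref"])
    flip = (merged["EA"] == merged["OA_ref"]) & (merged["OA"] == merged["EA_ref"])
    bad = ~(same | flip)
    if bad.any():
        log.info("dropping %d variants with unresolvable alleles", int(bad.sum()))
        merged = merged.loc[~bad]
        same, flip = same[~bad], flip[~bad]
    merged.loc[flip, "BETA"] = -merged.loc[flip, "BETA"]
    if "EAF" in merged.columns:
        merged.loc[flip, "EAF"] = 1.0 - merged.loc[flip, "EAF"]
    merged["EA"] = merged.pop("EA_ref")
    merged["OA"] = merged.pop("OA_ref")
    if drop_ambiguous:
        amb = [tuple(x) in _AMBIGUOUS for x in merged[["EA", "OA"]].to_numpy()]
        merged = merged.loc[~np.asarray(amb)]
    return merged


def fixed_effects_meta(tables: list[pd.DataFrame],
                       drop_ambiguous: bool = False) -> pd.DataFrame:
    """Inverse-variance fixed-effects meta-analysis across studies.

    pooled beta = sum(beta_s / se_s^2) / sum(1 / se_s^2);
    pooled se   = sqrt(1 / sum(1 / se_s^2)).
    Per-variant effective N is the sum over contributing studies; alleles are
    harmonised to the first study's orientation.
    """
    if not tables:
        raise ValueError("no tables to meta-analyse")
    ref = tables[0]
    aligned = [ref] + [_harmonize(ref, t, drop_ambiguous) for t in tables[1:]]
    stacked = pd.concat([t.assign(_study=i) for i, t in enumerate(aligned)],
                        ignore_index=True)
    stacked = stacked.loc[stacked["SE"].notna() & (stacked["SE"] > 0)]
    w = 1.0 / stacked["SE"] ** 2
    stacked = stacked.assign(_w=w, _wb=w * stacked["BETA"])
    spec = {"CHR": ("CHR", "first"), "BP": ("BP", "first"),
            "EA": ("EA", "first"), "OA": ("OA", "first"),
            "_w": ("_w", "sum"), "_wb": ("_wb", "sum"),
            "N": ("N", "sum"), "N_STUDIES": ("_study", "nunique")}
    if "EAF" in stacked.columns:
        spec["EAF"] = ("EAF", "mean")
    if "EFF_N" in stacked.columns:
        spec["EFF_N"] = ("EFF_N", "sum")
    agg = stacked.groupby("SNP", sort=False).agg(**spec).reset_index()
    agg["BETA"] = agg["_wb"] / agg["_w"]
    agg["SE"] = np.sqrt(1.0 / agg["_w"])
    from scipy import stats
    agg["P"] = 2 * stats.norm.sf(np.abs(agg["BETA"] / agg["SE"]))
    if "MODEL" in stacked.columns:
        agg["MODEL"] = stacked["MODEL"].iloc[0]
    cols = [c for c in ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE",
                        "P", "N", "EFF_N", "N_STUDIES", "MODEL"]
            if c in agg.columns]
    return agg[cols].sort_values(["CHR", "BP"], kind="stable"
                                 ).reset_index(drop=True)
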