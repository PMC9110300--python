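"""Polygenic adaptation testing with trait-aligned singleton density scores.

Raw SDS are normalized within 1% derived-allele-frequency bins, regions under
strong recent selection (MHC, lactase) are excluded, variants with low
effective sample size are removed, SDS are signed to the trait-increasing
allele (tSDS), and Spearman's rank correlation between tSDS and |Z| is tested
with a 100-block genomic jackknife.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .jackknife import block_bounds, jackknife_se

log = logging.getLogger(__name__)

#: 1-based inclusive intervals under strong recent selection (GRCh37)
SELECTED_REGIONS = (
    (6, 25_892_529, 33_436_144),    # MHC
    (2, 134_608_646, 138_608_646),  # lactase
)


def exclude_selected_regions(table: pd.DataFrame,
                             regions=SELECTED_REGIONS) -> pd.DataFrame:
    """Drop variants inside the excluded intervals (1-based inclusive)."""
    chrom = table["CHR"].to_numpy()
    bp = table["BP"].to_numpy()
    drop = np.zeros(len(table), dtype=bool)
    for c, start, end in regions:
        drop |= (chrom == c) & (bp >= start) & (bp <= end)
    return table.loc[~drop].reset_index(drop=True)


def normalize_sds(table: pd.DataFrame, freq_col: str = "DAF",
                  sds_col: str = "SDS") -> pd.DataFrame:
    """Standardize SDS to mean 0, SD 1 within each 1% frequency bin.

    Bins are half-open [k/100, (k+1)/100) with the final bin closed at 1.
    Bins holding fewer than 2 variants are passed through unchanged and
    flagged in the ``SDS_BIN_FLAG`` column.
    """
    daf = table[freq_col].to_numpy(dtype=float)
    if np.any((daf <= 0) | (daf >= 1)):
        raise ValueError("derived-allele frequencies must be in (0, 1)")
    out = table.copy()
    bins = np.minimum((daf * 100).astype(int), 99)
    sds = out[sds_col].to_numpy(dtype=float).copy()
    flag = np.zeros(len(out), dtype=bool)
    for b in np.unique(bins):
        idx = bins == b
        if idx.sum() < 2:
            flag[idx] = True
            continue
        vals = sds[idx]
        sd = vals.std(ddof=1)
        sds[idx] = (vals - vals.mean()) / sd if sd > 0 else 0.0
    out[sds_col] = sds
    out["SDS_BIN_FLAG"] = flag
    return out


def filter_low_effective_n(table: pd.DataFrame, threshold: float = 0.5,
                           eff_n_col: str = "EFF_N") -> pd.DataFrame:
    """Remove variants with effective N strictly below threshold * maximum."""
    eff = table[eff_n_col].to_numpy(dtype=float)
    keep = eff >= threshold * np.nanmax(eff)
    return table.loc[keep].reset_index(drop=True)


def align_tsds(sds_table: pd.DataFrame, gwas_table: pd.DataFrame
               ) -> pd.DataFrame:
    """Merge SDS with GWAS results and sign SDS to the trait-increasing allele.

    tSDS = SDS when the GWAS effect of the SDS derived allele is positive and
    -SDS when negative; beta exactly 0 is left unflipped and flagged. Variants
    whose alleles cannot be matched are dropped with a log entry.
    """
    merged = sds_table.merge(gwas_table, on="SNP", suffixes=("_sds", ""))
    same = (merged["DA"] == merged["EA"]) & (merged["AA"] == merged["OA"])
    swap = (merged["DA"] == merged["OA"]) & (merged["AA"] == merged["EA"])
    bad = ~(same | swap)
    if bad.any():
        log.info("tSDS alignment: dropped %d allele-mismatched variants",
                 int(bad.sum()))
        merged = merged.loc[~bad].reset_index(drop=True)
        same, swap = same[~bad].to_numpy(), swap[~bad].to_numpy()
    beta_da = merged["BETA"].to_numpy() * np.where(swap, -1.0, 1.0)
    merged["TSDS"] = np.where(beta_da < 0, -merged["SDS"], merged["SDS"])
    merged["TSDS_TIE"] = beta_da == 0
    merged["ABS_Z"] = np.abs(merged["BETA"] / merged["SE"])
    return merged


@dataclass
class AdaptationResult:
    rho: float
    se: float
    p: float
    n_variants: int
    model: str = ""
    n_blocks: int = 100
    mean_tsds_top: float = np.nan

    @property
    def z(self):
        return self.rho / self.se

    def summary(self) -> str:
        return (f"tSDS adaptation test ({self.model or 'gwas'}): "
                f"Spearman rho = {self.rho:.4f} (SE {self.se:.4f}), "
                f"p = {self.p:.3g}, variants = {self.n_variants}")


def _spearman(a_rank_input, b_rank_input):
    ra = stats.rankdata(a_rank_input)
    rb = stats.rankdata(b_rank_input)
    ra -= ra.mean()
    rb -= rb.mean()
    denom = np.sqrt(np.sum(ra**2) * np.sum(rb**2))
    if denom == 0:
        raise ValueError("constant input vector: correlation undefined")
    return float(np.sum(ra * rb) / denom)


def tsds_correlation(tsds, abs_z, chrom=None, bp=None, n_blocks: int = 100,
                     model: str = "") -> AdaptationResult:
    """Spearman correlation of tSDS with |Z| and its block-jackknife SE.

    Inputs are ordered by (chromosome, base pair) when coordinates are given;
    blocks are contiguous in that order. The p-value comes from the jackknife
    Z statistic rho / se.
    """
    tsds = np.asarray(tsds, dtype=float)
    abs_z = np.asarray(abs_z, dtype=float)
    if len(tsds) != len(abs_z):
        raise ValueError("tsds and abs_z must align")
    if chrom is not None:
        order = np.lexsort((np.asarray(bp), np.asarray(chrom)))
        tsds, abs_z = tsds[order], abs_z[order]
    rho = _spearman(tsds, abs_z)
    edges = block_bounds(len(tsds), n_blocks)
    loo = np.empty(len(edges) - 1)
    for k in range(len(edges) - 1):
        mask = np.ones(len(tsds), dtype=bool)
        mask[edges[k]:edges[k + 1]] = False
        loo[k] = _spearman(tsds[mask], abs_z[mask])
    se = jackknife_se(loo)
    z = rho / se if se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0
    return AdaptationResult(rho=rho, se=se, p=p, n_variants=len(tsds),
                            model=model, n_blocks=len(edges) - 1)


def mean_tsds_at_hits(table: pd.DataFrame, p_threshold: float = 1e-5
                      ) -> float:
    """Mean tSDS at strongly associated variants (positive under selection)."""
    hits = table.loc[table["P"] < p_threshold]
    if hits.empty:
        return np.nan
    return float(hits["TSDS"].mean())
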