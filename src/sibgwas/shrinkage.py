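"""Weighted scores and the population-to-within-sibship shrinkage estimator.

For a set of M independent discovery-selected variants with discovery weights
w_k and target-sample estimates (beta_k, sigma_k), the summary-based weighted
score is

    S       = sum(w_k beta_k / sigma_k^2) / sum(w_k^2 / sigma_k^2)
    sigma_S = sqrt(1 / sum(w_k^2 / sigma_k^2))

which equals the no-intercept weighted-least-squares slope of beta on w with
weights 1/sigma^2. Shrinkage between the within-sibship and population scores
is delta = 1 - S_W / S_P (reported in %), with its SE from a leave-one-variant-
out jackknife because the two scores come from separate fits with unknown
covariance.

Weights must come from a discovery sample disjoint from the target cohort;
a provenance label check guards against winner's curse by sample overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .jackknife import jackknife_se

log = logging.getLogger(__name__)

GENOME_WIDE = 5e-8
LIBERAL = 1e-5   # primary reporting threshold


@dataclass
class InstrumentSet:
    """Discovery-selected, mutually independent variants with their weights."""

    snps: list
    weights: np.ndarray
    p_threshold: float
    source: str = "discovery"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.snps) != len(self.weights):
            raise ValueError("snps and weights must align")
        if len(self.weights) and (~np.isfinite(self.weights) |
                                  (self.weights == 0)).any():
            raise ValueError("weights must be finite and nonzero")

    def __len__(self):
        return len(self.snps)


def select_instruments(discovery: pd.DataFrame, p_threshold: float = LIBERAL,
                       r2: np.ndarray | pd.DataFrame | None = None,
                       r2_threshold: float = 0.001,
                       window_kb: float = 10_000,
                       source: str = "discovery") -> InstrumentSet:
    """Greedy LD clumping: ascending p, drop anything correlated with a keeper.

    ``r2`` is a square matrix aligned to the rows of ``discovery`` (or indexed
    by SNP if a DataFrame). Variants are excluded when their r^2 with any
    retained variant reaches ``r2_threshold`` within ``window_kb`` of it; with
    no LD information, variants are treated as independent and only the
    p-value threshold applies.
    """
    d = discovery.reset_index(drop=True)
    pvals = d["P"].to_numpy()
    cand = np.flatnonzero(pvals < p_threshold)
    if len(cand) == 0:
        warnings.warn("no variant passes the p-value threshold")
        return InstrumentSet(snps=[], weights=np.empty(0),
                             p_threshold=p_threshold, source=source)
    cand = cand[np.argsort(pvals[cand], kind="stable")]
    if r2 is None:
        kept = list(cand)
    else:
        if isinstance(r2, pd.DataFrame):
            r2 = r2.loc[d["SNP"], d["SNP"]].to_numpy()
        r2 = np.asarray(r2, dtype=float)
        chrom = d["CHR"].to_numpy()
        bp = d["BP"].to_numpy()
        kept = []
        for i in cand:
            clash = False
            for j in kept:
                close = (chrom[i] == chrom[j]
                         and abs(bp[i] - bp[j]) <= window_kb * 1000)
                if close and r2[i, j] >= r2_threshold:
                    clash = True
                    break
            if not clash:
                kept.append(i)
    return InstrumentSet(snps=list(d["SNP"].iloc[kept]),
                         weights=d["BETA"].to_numpy()[kept],
                         p_threshold=p_threshold, source=source)


@dataclass
class WeightedScore:
    S: float
    sigma_S: float
    M: int
    model: str = ""
    threshold: str = ""

    @property
    def z(self) -> float:
        return self.S / self.sigma_S


def weighted_score(betas, ses, weights, model: str = "",
                   threshold: str = "") -> WeightedScore:
    """Inverse-variance weighted score of target betas against discovery weights."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (len(betas) == len(ses) == len(w)):
        raise ValueError("inputs must have equal length")
    if len(betas) == 0:
        raise ValueError("empty instrument set")
    if np.any(ses <= 0):
        raise ValueError("ses must be positive")
    denom = np.sum(w**2 / ses**2)
    s = np.sum(w * betas / ses**2) / denom
    return WeightedScore(S=float(s), sigma_S=float(np.sqrt(1.0 / denom)),
                         M=len(betas), model=model, threshold=threshold)


def shrinkage_estimate(s_within: WeightedScore, s_population: WeightedScore,
                       cov: float | None = None):
    """Point estimate delta = 1 - S_W / S_P with an optional delta-method SE.

    Returns (delta, delta_method_se or None, flags). A population score with
    |Z| < 2 makes the ratio unstable and is flagged.
    """
    if s_population.S == 0:
        raise ZeroDivisionError("population score is exactly zero")
    flags = []
    if abs(s_population.z) < 2:
        flags.append("unstable_denominator")
    delta = 1.0 - s_within.S / s_population.S
    se = None
    if cov is not None:
        ratio = s_within.S / s_population.S
        inner = (s_within.sigma_S**2 / s_within.S**2
                 + s_population.sigma_S**2 / s_population.S**2
                 - 2.0 * cov / (s_within.S * s_population.S))
        if inner < 0:
            raise ValueError("delta-method variance is negative")
        se = abs(ratio) * np.sqrt(inner)
    return delta, se, flags


class ShrinkageResults:
    """Shrinkage delta with jackknife SE, CI and across-variant heterogeneity."""

    def __init__(self, delta, se, loo, q, q_df, q_p, wald_ratios, m,
                 flags, delta_method_se=None):
        self.delta = delta
        self.se = se
        self.loo = loo
        self.delta_method_se = delta_method_se
        self.Q = q
        self.Q_df = q_df
        self.Q_p = q_p
        self.wald_ratios = wald_ratios
        self.M = m
        self.flags = flags

    @property
    def ci(self):
        return (self.delta - 1.96 * self.se, self.delta + 1.96 * self.se)

    @property
    def percent(self):
        return 100.0 * self.delta

    @property
    def p(self):
        return 2 * stats.norm.sf(abs(self.delta / self.se))

    def summary(self) -> str:
        lo, hi = self.ci
        lines = [
            f"shrinkage delta = {self.percent:.1f}% "
            f"(95% CI {100 * lo:.1f}%, {100 * hi:.1f}%), M = {self.M}",
            f"  jackknife SE = {100 * self.se:.2f}%   p = {self.p:.3g}",
        ]
        if np.isfinite(self.Q) and self.Q_df > 0:
            lines.append(f"  heterogeneity Q = {self.Q:.2f} "
                         f"(df {self.Q_df}), p = {self.Q_p:.3g}")
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)


class ShrinkageModel:
    """Estimate shrinkage between aligned population and within-sibship tables.

    Parameters are per-instrument arrays already aligned across the two models
    and the discovery weights; use :meth:`from_tables` to build them from
    association tables plus an :class:`InstrumentSet`.
    """

    def __init__(self, beta_pop, se_pop, beta_ws, se_ws, weights,
                 source: str | None = None, target: str | None = None):
        arrays = [np.asarray(a, dtype=float)
                  for a in (beta_pop, se_pop, beta_ws, se_ws, weights)]
        if len({len(a) for a in arrays}) != 1:
            raise ValueError("all inputs must have equal length")
        if source is not None and target is not None and source == target:
            raise ValueError("discovery weights must come from a sample "
                             "independent of the target cohort")
        (self.beta_pop, self.se_pop, self.beta_ws, self.se_ws,
         self.weights) = arrays
        self.M = len(self.weights)

    @classmethod
    def from_tables(cls, pop_table: pd.DataFrame, ws_table: pd.DataFrame,
                    instruments: InstrumentSet,
                    target: str | None = None) -> "ShrinkageModel":
        pop = pop_table.set_index("SNP")
        ws = ws_table.set_index("SNP")
        snps = [s for s in instruments.snps
                if s in pop.index and s in ws.index
                and np.isfinite(pop.at[s, "SE"]) and np.isfinite(ws.at[s, "SE"])]
        keep = [i for i, s in enumerate(instruments.snps) if s in set(snps)]
        return cls(pop.loc[snps, "BETA"], pop.loc[snps, "SE"],
                   ws.loc[snps, "BETA"], ws.loc[snps, "SE"],
                   instruments.weights[keep],
                   source=instruments.source, target=target)

    def _delta(self, mask) -> float:
        sw = weighted_score(self.beta_ws[mask], self.se_ws[mask],
                            self.weights[mask])
        sp = weighted_score(self.beta_pop[mask], self.se_pop[mask],
                            self.weights[mask])
        return 1.0 - sw.S / sp.S

    def fit(self, z_filter: float = 2.0) -> ShrinkageResults:
        if self.M < 2:
            raise ValueError("need at least 2 instruments for the jackknife")
        sw = weighted_score(self.beta_ws, self.se_ws, self.weights,
                            model="within_sibship")
        sp = weighted_score(self.beta_pop, self.se_pop, self.weights,
                            model="population")
        delta, dm_se, flags = shrinkage_estimate(sw, sp, cov=0.0)
        loo = np.array([self._delta(np.arange(self.M) != k)
                        for k in range(self.M)])
        se = jackknife_se(loo)
        q, q_df, q_p, s_k = heterogeneity_q(
            self.beta_pop, self.se_pop, self.beta_ws, self.se_ws,
            z_filter=z_filter)
        return ShrinkageResults(delta=delta, se=se, loo=loo, q=q, q_df=q_df,
                                q_p=q_p, wald_ratios=s_k, m=self.M,
                                flags=flags, delta_method_se=dm_se)


def jackknife_se_shrinkage(beta_pop, se_pop, beta_ws, se_ws, weights) -> float:
    """Leave-one-variant-out jackknife SE of delta (functional form)."""
    model = ShrinkageModel(beta_pop, se_pop, beta_ws, se_ws, weights)
    if model.M < 2:
        raise ValueError("need at least 2 instruments")
    loo = np.array([model._delta(np.arange(model.M) != k)
                    for k in range(model.M)])
    return jackknife_se(loo)


def heterogeneity_q(beta_pop, se_pop, beta_ws, se_ws, z_filter: float = 2.0):
    """Across-variant heterogeneity of per-variant shrinkage Wald ratios.

    s_k = beta_P,k / beta_W,k is compared with the precision-weighted combined
    ratio S using Cochran's Q with delta-method ratio variances

        var(s_k) = (sigma_P,k^2 + S^2 sigma_W,k^2) / beta_W,k^2.

    Variants with |Z_W| <= z_filter are removed first (logged): weak
    denominators make the ratio explode. Returns (Q, df, p, s_k series);
    a single retained variant gives Q = 0, df = 0, p = NaN.
    """
    beta_pop, se_pop, beta_ws, se_ws = (np.asarray(a, dtype=float) for a in
                                        (beta_pop, se_pop, beta_ws, se_ws))
    keep = np.abs(beta_ws / se_ws) > z_filter
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("heterogeneity: removed %d weak-denominator variants", n_drop)
    if keep.sum() == 0:
        raise ValueError("all variants removed by the |Z| filter")
    bp, sp_, bw, sw_ = (a[keep] for a in (beta_pop, se_pop, beta_ws, se_ws))
    s_k = bp / bw
    if len(s_k) == 1:
        return 0.0, 0, np.nan, s_k

    def _ratio_var(s):
        # delta-method variance of bp/bw with the second-order denominator
        # term; without it Q is anti-conservative at moderate |Z_W|
        first = (sp_**2 + s**2 * sw_**2) / bw**2
        second = 3.0 * (sw_**2 / bw**2) * (sp_**2 + 3.0 * s**2 * sw_**2) \
            / (sp_**2 + s**2 * sw_**2)
        return first * (1.0 + second)

    # two-pass: centre the ratio variance on the combined ratio, then test
    w0 = 1.0 / _ratio_var(s_k)
    s_comb = float(np.sum(w0 * s_k) / np.sum(w0))
    w = 1.0 / _ratio_var(s_comb)
    s_comb = float(np.sum(w * s_k) / np.sum(w))
    q = float(np.sum(w * (s_k - s_comb) ** 2))
    df = len(s_k) - 1
    return q, df, float(stats.chi2.sf(q, df)), s_k


def study_level_heterogeneity(study_deltas, study_ses):
    """Cochran's Q across per-study shrinkage estimates. Returns (Q, df, p)."""
    d = np.asarray(study_deltas, dtype=float)
    se = np.asarray(study_ses, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 studies")
    w = 1.0 / se**2
    mean = np.sum(w * d) / np.sum(w)
    q = float(np.sum(w * (d - mean) ** 2))
    df = len(d) - 1
    return q, df, float(stats.chi2.sf(q, df))
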