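"""Inverse-variance-weighted Mendelian randomization from summary statistics.

With aligned instruments (same variants and effect alleles in the exposure and
outcome GWAS),

    beta_MR = sum(beta_Exp * beta_Out / se_Out^2) / sum(beta_Exp^2 / se_Out^2)
    se_MR   = sqrt(1 / sum(beta_Exp^2 / se_Out^2))

the fixed-effect IVW estimator with first-order weights (exposure SEs do not
enter the denominator). Population and within-sibship MR estimates are
compared with a leave-one-variant-out jackknife difference test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .jackknife import jackknife_se

log = logging.getLogger(__name__)


@dataclass
class MrResult:
    beta: float
    se: float
    n_instruments: int
    model: str = ""
    wald_ratios: np.ndarray = field(default=None, repr=False)
    q: float = np.nan
    q_p: float = np.nan

    @property
    def z(self):
        return self.beta / self.se

    @property
    def p(self):
        return float(2 * stats.norm.sf(abs(self.z)))

    @property
    def ci(self):
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)

    @property
    def overdispersed(self) -> bool:
        """Cochran's Q across Wald ratios well beyond its df."""
        return bool(np.isfinite(self.q_p) and self.q_p < 0.05)

    def summary(self) -> str:
        lo, hi = self.ci
        s = (f"IVW MR ({self.model or 'summary'}): beta = {self.beta:.4f} "
             f"(95% CI {lo:.4f}, {hi:.4f}), p = {self.p:.3g}, "
             f"instruments = {self.n_instruments}")
        if self.overdispersed:
            s += f"\n  note: heterogeneity Q p = {self.q_p:.3g} (overdispersion)"
        return s


class IvwMr:
    """Fixed-effect IVW MR model over aligned per-instrument estimates."""

    def __init__(self, beta_exp, beta_out, se_out, model: str = ""):
        self.beta_exp = np.asarray(beta_exp, dtype=float)
        self.beta_out = np.asarray(beta_out, dtype=float)
        self.se_out = np.asarray(se_out, dtype=float)
        if not (len(self.beta_exp) == len(self.beta_out) == len(self.se_out)):
            raise ValueError("instrument arrays must align")
        if len(self.beta_exp) == 0:
            raise ValueError("zero instruments")
        if np.all(self.beta_exp == 0):
            raise ValueError("all exposure effects are zero")
        if np.any(self.se_out <= 0):
            raise ValueError("outcome SEs must be positive")
        self.model = model

    @classmethod
    def from_tables(cls, exposure: pd.DataFrame, outcome: pd.DataFrame,
                    instruments=None, model: str = "") -> "IvwMr":
        exp = exposure.set_index("SNP")
        out = outcome.set_index("SNP")
        snps = [s for s in (instruments.snps if instruments is not None
                            else exp.index) if s in exp.index and s in out.index]
        flip = exp.loc[snps, "EA"].to_numpy() != out.loc[snps, "EA"].to_numpy()
        b_out = out.loc[snps, "BETA"].to_numpy() * np.where(flip, -1.0, 1.0)
        return cls(exp.loc[snps, "BETA"], b_out, out.loc[snps, "SE"],
                   model=model)

    def fit(self) -> MrResult:
        w = self.beta_exp**2 / self.se_out**2
        denom = w.sum()
        beta = float(np.sum(self.beta_exp * self.beta_out / self.se_out**2)
                     / denom)
        se = float(np.sqrt(1.0 / denom))
        nz = self.beta_exp != 0
        wald = np.full(len(self.beta_exp), np.nan)
        wald[nz] = self.beta_out[nz] / self.beta_exp[nz]
        q = float(np.nansum(w[nz] * (wald[nz] - beta) ** 2))
        q_df = int(nz.sum()) - 1
        q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else np.nan
        if q_df > 0 and q_p < 0.05:
            log.info("MR heterogeneity Q=%.2f df=%d p=%.3g: possible "
                     "overdispersion; fixed-effect SE reported", q, q_df, q_p)
        return MrResult(beta=beta, se=se, n_instruments=len(self.beta_exp),
                        model=self.model, wald_ratios=wald, q=q, q_p=q_p)


def mr_ivw(beta_exp, beta_out, se_out, model: str = "") -> MrResult:
    """Functional wrapper over :class:`IvwMr`."""
    return IvwMr(beta_exp, beta_out, se_out, model=model).fit()


@dataclass
class MrDifference:
    diff: float
    se: float
    z: float
    p: float
    n_instruments: int
    beta_pop: float
    beta_ws: float


def mr_difference_jackknife(beta_exp_pop, beta_out_pop, se_out_pop,
                            beta_exp_ws, beta_out_ws, se_out_ws
                            ) -> MrDifference:
    """Leave-one-variant-out jackknife test of beta_MR,Pop - beta_MR,WS."""
    pop = IvwMr(beta_exp_pop, beta_out_pop, se_out_pop, model="population")
    ws = IvwMr(beta_exp_ws, beta_out_ws, se_out_ws, model="within_sibship")
    n = len(pop.beta_exp)
    if len(ws.beta_exp) != n:
        raise ValueError("population and within-sibship instruments must align")
    if n < 2:
        raise ValueError("need at least 2 instruments")
    full_pop, full_ws = pop.fit().beta, ws.fit().beta

    def _ivw_loo(be, bo, so):
        num = be * bo / so**2
        den = be**2 / so**2
        return (num.sum() - num) / (den.sum() - den)

    loo = _ivw_loo(pop.beta_exp, pop.beta_out, pop.se_out) \
        - _ivw_loo(ws.beta_exp, ws.beta_out, ws.se_out)
    se = jackknife_se(loo)
    diff = full_pop - full_ws
    z = diff / se if se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0
    return MrDifference(diff=diff, se=se, z=z, p=p, n_instruments=n,
                        beta_pop=full_pop, beta_ws=full_ws)
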