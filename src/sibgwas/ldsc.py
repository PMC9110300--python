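"""Minimal LD score regression: h2, intercept, confounding ratio, rg.

Model: for variant j with LD score l_j,

    E[chi2_j] = N h2 l_j / M + N a + 1

so the slope of a weighted regression of chi2 on l_j recovers h2 = slope*M/N
and the intercept 1 + N a captures confounding; the ratio
(intercept - 1)/(mean chi2 - 1) is the fraction of inflation attributable to
confounding. Cross-trait: E[z1 z2] = sqrt(N1 N2) rg sqrt(h2_1 h2_2) l_j / M +
overlap intercept. Standard errors come from a block jackknife over contiguous
blocks in (chromosome, position) order.

Weighting: 1/max(l_j, 1) initially, then one reweighting pass with
1/(max(l_j,1) * fitted^2) where fitted is the first-pass mean; weights are
estimated once on the full data and held fixed across jackknife blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .jackknife import block_bounds, jackknife_se


class _BlockWls:
    """2-parameter WLS of y on [1, x] with O(1) leave-one-block-out solves."""

    def __init__(self, x, w, n_blocks):
        x = np.asarray(x, dtype=float)
        w = np.asarray(w, dtype=float)
        self.edges = block_bounds(len(x), n_blocks)
        self.n_blocks = len(self.edges) - 1
        xw = np.column_stack([w, w * x, w * x * x])
        self._a_blocks = np.add.reduceat(xw, self.edges[:-1], axis=0)
        self._a_total = self._a_blocks.sum(axis=0)
        self._x, self._w = x, w

    def _solve(self, a, c):
        s0, s1, s2 = a
        det = s0 * s2 - s1 * s1
        return np.array([(s2 * c[0] - s1 * c[1]) / det,
                         (s0 * c[1] - s1 * c[0]) / det])

    def coef(self, y):
        """(intercept, slope) on the full data."""
        c = np.array([np.sum(self._w * y), np.sum(self._w * self._x * y)])
        return self._solve(self._a_total, c)

    def coef_loo(self, y):
        """(n_blocks, 2) array of leave-one-block-out (intercept, slope)."""
        yw = np.column_stack([self._w * y, self._w * self._x * y])
        c_blocks = np.add.reduceat(yw, self.edges[:-1], axis=0)
        c_total = c_blocks.sum(axis=0)
        out = np.empty((self.n_blocks, 2))
        for b in range(self.n_blocks):
            out[b] = self._solve(self._a_total - self._a_blocks[b],
                                 c_total - c_blocks[b])
        return out


def _ldsc_weights(chi2, l2):
    lf = np.maximum(l2, 1.0)
    w0 = 1.0 / lf
    # first pass on provisional weights, then reweight by fitted mean^2
    coef = _BlockWls(l2, w0, 2).coef(chi2)
    fitted = np.maximum(coef[0] + coef[1] * l2, 1.0)
    return 1.0 / (lf * fitted**2)


@dataclass
class LdscFit:
    intercept: float
    intercept_se: float
    slope: float
    h2: float
    h2_se: float
    mean_chi2: float
    ratio: float
    ratio_se: float
    n_blocks: int
    M: int
    N: float
    flags: list

    def summary(self) -> str:
        lines = [
            f"LD score regression (M = {self.M}, N = {self.N:g}, "
            f"{self.n_blocks} jackknife blocks)",
            f"  h2        = {self.h2:.4f} (SE {self.h2_se:.4f})",
            f"  intercept = {self.intercept:.4f} (SE {self.intercept_se:.4f})",
            f"  mean chi2 = {self.mean_chi2:.4f}",
        ]
        if np.isfinite(self.ratio):
            lines.append(f"  ratio     = {self.ratio:.4f} (SE {self.ratio_se:.4f})")
        else:
            lines.append("  ratio     = undefined (mean chi2 <= 1)")
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)


class LdscModel:
    """Univariate LD score regression on per-variant chi-square statistics.

    Inputs must already be sorted by (chromosome, base pair); blocks for the
    jackknife are contiguous spans with near-equal variant counts.
    """

    def __init__(self, chi2, ldscores, n, m: int | None = None,
                 n_blocks: int = 100):
        self.chi2 = np.asarray(chi2, dtype=float)
        self.l2 = np.asarray(ldscores, dtype=float)
        if len(self.chi2) != len(self.l2):
            raise ValueError("chi2 and ldscores must align")
        if n <= 0:
            raise ValueError("effective n must be positive")
        self.n = float(n)
        self.m = len(self.chi2) if m is None else int(m)
        self.n_blocks = n_blocks

    @classmethod
    def from_table(cls, table: pd.DataFrame, n=None, m=None, n_blocks=100):
        t = table.sort_values(["CHR", "BP"], kind="stable")
        chi2 = t["CHI2"].to_numpy() if "CHI2" in t else t["Z"].to_numpy() ** 2
        n = float(t["N"].median()) if n is None else n
        return cls(chi2, t["L2"].to_numpy(), n=n, m=m, n_blocks=n_blocks)

    def fit(self) -> LdscFit:
        w = _ldsc_weights(self.chi2, self.l2)
        eng = _BlockWls(self.l2, w, self.n_blocks)
        coef = eng.coef(self.chi2)
        loo = eng.coef_loo(self.chi2)
        scale = self.m / self.n
        h2 = coef[1] * scale
        h2_se = jackknife_se(loo[:, 1] * scale)
        intercept_se = jackknife_se(loo[:, 0])
        mean_chi2 = float(self.chi2.mean())
        # leave-one-block mean chi2 for the ratio jackknife
        counts = np.diff(eng.edges)
        sums = np.add.reduceat(self.chi2, eng.edges[:-1])
        loo_mean = (self.chi2.sum() - sums) / (len(self.chi2) - counts)
        flags = []
        ratio, ratio_se = np.nan, np.nan
        if mean_chi2 > 1.0:
            raw = (coef[0] - 1.0) / (mean_chi2 - 1.0)
            if not (0.0 <= raw <= 1.0):
                flags.append("ratio_clipped")
            ratio = float(np.clip(raw, 0.0, 1.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                loo_ratio = (loo[:, 0] - 1.0) / (loo_mean - 1.0)
            ratio_se = jackknife_se(loo_ratio)
        else:
            flags.append("ratio_undefined")
        return LdscFit(intercept=float(coef[0]), intercept_se=intercept_se,
                       slope=float(coef[1]), h2=float(h2), h2_se=h2_se,
                       mean_chi2=mean_chi2, ratio=ratio, ratio_se=ratio_se,
                       n_blocks=eng.n_blocks, M=self.m, N=self.n, flags=flags)


def ldsc_fit(chi2, ldscores, effective_n, m=None, n_blocks=100) -> LdscFit:
    """Functional wrapper over :class:`LdscModel`."""
    return LdscModel(chi2, ldscores, n=effective_n, m=m,
                     n_blocks=n_blocks).fit()


def ldsc_ratio(fit: LdscFit) -> float:
    """(intercept - 1)/(mean chi2 - 1), the confounding share of inflation."""
    if fit.mean_chi2 <= 1.0:
        return np.nan
    return float(np.clip((fit.intercept - 1.0) / (fit.mean_chi2 - 1.0),
                         0.0, 1.0))


def expected_ws_h2(h2_pop: float, k: float) -> float:
    """Expected within-sibship h2 when Z scores shrink uniformly by (1 - k)."""
    if not (0.0 <= k <= 1.0):
        raise ValueError("shrinkage coefficient k must be in [0, 1]")
    return (1.0 - k) ** 2 * h2_pop


@dataclass
class DifferenceTest:
    diff: float
    se: float
    z: float
    p: float


def h2_difference_test(pop, ws, cross_intercept: float) -> DifferenceTest:
    """Difference-of-two-means test with Cov = Cor * se_pop * se_ws.

    The cross-GWAS LD score intercept estimates the sampling correlation
    between the two h2 estimates from overlapping samples.
    """
    h2_p, se_p = (pop.h2, pop.h2_se) if hasattr(pop, "h2") else pop
    h2_w, se_w = (ws.h2, ws.h2_se) if hasattr(ws, "h2") else ws
    if se_p <= 0 or se_w <= 0:
        raise ValueError("standard errors must be positive")
    if abs(cross_intercept) >= 1:
        raise ValueError("|cross intercept| must be < 1")
    var = se_p**2 + se_w**2 - 2.0 * cross_intercept * se_p * se_w
    if var <= 0:
        raise ValueError("implied difference variance is not positive")
    diff = h2_p - h2_w
    se = float(np.sqrt(var))
    z = diff / se
    return DifferenceTest(diff=diff, se=se, z=z,
                          p=float(2 * stats.norm.sf(abs(z))))


@dataclass
class RgResult:
    rg: float
    se: float
    gencov: float
    cross_intercept: float
    h2_1: float
    h2_2: float
    n_blocks: int
    flags: list

    @property
    def z(self):
        return self.rg / self.se

    @property
    def p(self):
        return float(2 * stats.norm.sf(abs(self.z)))

    def summary(self) -> str:
        lines = [f"cross-trait LDSC rg = {self.rg:.4f} (SE {self.se:.4f}), "
                 f"p = {self.p:.3g}",
                 f"  genetic covariance = {self.gencov:.4g}; "
                 f"cross intercept = {self.cross_intercept:.4f}",
                 f"  h2: {self.h2_1:.4f} / {self.h2_2:.4f}"]
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)


class CrossTraitLdsc:
    """Cross-trait LD score regression of z1*z2 on LD scores.

    rg = gencov / sqrt(h2_1 * h2_2) where each h2 comes from the univariate
    fit on the same panel; SE by the shared block jackknife, so the three
    regressions are consistently recomputed per left-out block.
    """

    def __init__(self, z1, z2, ldscores, n1, n2, m=None, n_blocks=100):
        self.z1 = np.asarray(z1, dtype=float)
        self.z2 = np.asarray(z2, dtype=float)
        self.l2 = np.asarray(ldscores, dtype=float)
        if not (len(self.z1) == len(self.z2) == len(self.l2)):
            raise ValueError("z1, z2 and ldscores must align")
        self.n1, self.n2 = float(n1), float(n2)
        self.m = len(self.z1) if m is None else int(m)
        self.n_blocks = n_blocks

    def _rg_path(self):
        chi1, chi2_, prod = self.z1**2, self.z2**2, self.z1 * self.z2
        w1 = _ldsc_weights(chi1, self.l2)
        w2 = _ldsc_weights(chi2_, self.l2)
        wx = np.sqrt(w1 * w2)
        eng1 = _BlockWls(self.l2, w1, self.n_blocks)
        eng2 = _BlockWls(self.l2, w2, self.n_blocks)
        engx = _BlockWls(self.l2, wx, self.n_blocks)
        return chi1, chi2_, prod, eng1, eng2, engx

    @staticmethod
    def _rg_from(coef1, coef2, coefx, m, n1, n2):
        h2_1 = coef1[..., 1] * m / n1
        h2_2 = coef2[..., 1] * m / n2
        gencov = coefx[..., 1] * m / np.sqrt(n1 * n2)
        # h2 at numerical zero (or below) leaves rg undefined
        denom = np.where((h2_1 > 1e-10) & (h2_2 > 1e-10), h2_1 * h2_2, np.nan)
        with np.errstate(invalid="ignore"):
            rg = gencov / np.sqrt(denom)
        return h2_1, h2_2, gencov, rg

    def fit(self) -> RgResult:
        chi1, chi2_, prod, eng1, eng2, engx = self._rg_path()
        c1, c2, cx = eng1.coef(chi1), eng2.coef(chi2_), engx.coef(prod)
        h2_1, h2_2, gencov, rg = self._rg_from(c1, c2, cx, self.m,
                                               self.n1, self.n2)
        flags = []
        if not np.isfinite(rg):
            flags.append("rg_undefined_nonpositive_h2")
            return RgResult(rg=np.nan, se=np.nan, gencov=float(gencov),
                            cross_intercept=float(cx[0]), h2_1=float(h2_1),
                            h2_2=float(h2_2), n_blocks=eng1.n_blocks,
                            flags=flags)
        l1, l2_, lx = (eng1.coef_loo(chi1), eng2.coef_loo(chi2_),
                       engx.coef_loo(prod))
        _, _, _, rg_loo = self._rg_from(l1, l2_, lx, self.m, self.n1, self.n2)
        good = np.isfinite(rg_loo)
        if not good.all():
            warnings.warn("some jackknife blocks gave undefined rg; "
                          "se uses the finite blocks")
        if good.sum() < 2:
            flags.append("rg_se_undefined")
            return RgResult(rg=float(rg), se=np.nan, gencov=float(gencov),
                            cross_intercept=float(cx[0]), h2_1=float(h2_1),
                            h2_2=float(h2_2), n_blocks=eng1.n_blocks,
                            flags=flags)
        se = jackknife_se(rg_loo[good])
        if abs(rg) > 1.25:
            flags.append("rg_out_of_range")
        return RgResult(rg=float(rg), se=se, gencov=float(gencov),
                        cross_intercept=float(cx[0]), h2_1=float(h2_1),
                        h2_2=float(h2_2), n_blocks=eng1.n_blocks, flags=flags)


def cross_trait_rg(z1, z2, ldscores, n1, n2, n_blocks=100) -> RgResult:
    """Functional wrapper over :class:`CrossTraitLdsc`."""
    return CrossTraitLdsc(z1, z2, ldscores, n1, n2, n_blocks=n_blocks).fit()


def rg_difference_jackknife(pop_inputs, ws_inputs, ldscores,
                            n_blocks: int = 100) -> DifferenceTest:
    """Block-jackknife difference between population and within-sibship rg.

    ``pop_inputs`` and ``ws_inputs`` are (z1, z2, n1, n2) tuples on the same
    variant panel (sorted by chromosome/position) as ``ldscores``.
    """
    l2 = np.asarray(ldscores, dtype=float)
    if len(l2) < 200:
        raise ValueError("need at least 200 variants for a block jackknife")

    def _paths(inputs):
        z1, z2, n1, n2 = inputs
        model = CrossTraitLdsc(z1, z2, l2, n1, n2, n_blocks=n_blocks)
        chi1, chi2_, prod, e1, e2, ex = model._rg_path()
        full = model._rg_from(e1.coef(chi1), e2.coef(chi2_), ex.coef(prod),
                              model.m, model.n1, model.n2)[3]
        loo = model._rg_from(e1.coef_loo(chi1), e2.coef_loo(chi2_),
                             ex.coef_loo(prod), model.m, model.n1,
                             model.n2)[3]
        return float(full), loo

    rg_pop, loo_pop = _paths(pop_inputs)
    rg_ws, loo_ws = _paths(ws_inputs)
    diff = rg_pop - rg_ws
    loo_diff = loo_pop - loo_ws
    good = np.isfinite(loo_diff)
    se = jackknife_se(loo_diff[good])
    z = diff / se if se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0
    return DifferenceTest(diff=diff, se=se, z=z, p=p)
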