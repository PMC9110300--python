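"""Population and within-sibship association models.

Per variant, two linear models are fitted on identical samples:

* population:       y ~ G + covariates
* within-sibship:   y ~ G^C + G^F + covariates

where ``G^F`` is the mean genotype of the study-present siblings in the
sibship and ``G^C = G - G^F`` the individual's deviation from it. The reported
within-sibship effect is the ``G^C`` coefficient; the ``G^F`` coefficient is
retained as auxiliary output. Standard errors are clustered over sibships
(CR0 sandwich with a G/(G-1) small-sample factor); an unclustered option is
kept for diagnostics because naive SEs are anti-conservative in family data.

Fits are closed-form and vectorised across variants (Frisch-Waugh-Lovell:
phenotype and genotype terms are residualised on the covariates once, then
per-variant slopes and cluster sandwiches are accumulated in chunks), which is
numerically identical to the full OLS fit per variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SibshipCohort


# ----------------------------------------------------------------- QC rules
def apply_missingness_rule(cohort: SibshipCohort, phenotype_name: str
                           ) -> SibshipCohort:
    """Set a sibship's phenotype fully missing when <2 members are observed.

    A sibship with a single non-missing phenotype value contributes no
    within-family contrast, so its remaining value is removed to keep the
    population and within-sibship models on identical samples.
    """
    if phenotype_name not in cohort.phenotypes.columns:
        raise KeyError(f"unknown phenotype {phenotype_name!r}")
    y = cohort.phenotypes[phenotype_name]
    n_obs = y.notna().groupby(cohort.samples["FID"].to_numpy()).transform("sum")
    new = cohort.phenotypes.copy()
    new[phenotype_name] = y.where(n_obs >= 2)
    return SibshipCohort(genotypes=cohort.genotypes, samples=cohort.samples,
                         variants=cohort.variants, phenotypes=new,
                         parent_genotypes=cohort.parent_genotypes,
                         truth=cohort.truth)


def qc_filter_variants(table: pd.DataFrame, maf_min: float = 0.01,
                       info_min: float = 0.3) -> pd.DataFrame:
    """Keep common (MAF > maf_min), well-imputed (INFO >= info_min) variants."""
    maf_col = "MAF" if "MAF" in table.columns else "EAF"
    maf = table[maf_col].to_numpy(dtype=float)
    maf = np.minimum(maf, 1.0 - maf)
    info = table["INFO"].to_numpy(dtype=float) if "INFO" in table.columns \
        else np.ones(len(table))
    keep = (maf > maf_min) & (info >= info_min)
    return table.loc[keep].reset_index(drop=True)


# ------------------------------------------------------------- centering op
@dataclass
class CenteredGenotypes:
    """Family means and within-family deviations; deviations sum to 0 exactly."""

    family_mean: np.ndarray   # (n_individuals, n_variants), G^F expanded to rows
    centered: np.ndarray      # (n_individuals, n_variants), G^C
    sibship_ids: np.ndarray


def center_genotypes(cohort_or_genotypes, sibship_ids=None) -> CenteredGenotypes:
    """Compute G^F (sibship mean) and G^C = G - G^F per variant.

    Accepts a :class:`SibshipCohort` or a raw (genotypes, sibship_ids) pair.
    Raises if any sibship has a single member: singletons carry no
    within-family information and must be excluded upstream.
    """
    if sibship_ids is None:
        cohort = cohort_or_genotypes
        g = np.asarray(cohort.genotypes, dtype=np.float64)
        fids = cohort.sibship_ids
    else:
        g = np.asarray(cohort_or_genotypes, dtype=np.float64)
        fids = np.asarray(sibship_ids)
    codes, _ = pd.factorize(fids)
    order = np.argsort(codes, kind="stable")
    if not np.array_equal(order, np.arange(len(codes))):
        raise ValueError("rows must be grouped by sibship; sort first")
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    sizes = np.diff(np.r_[starts, len(codes)])
    if (sizes < 2).any():
        raise ValueError("singleton sibship encountered; exclude upstream")
    fam_sum = np.add.reduceat(g, starts, axis=0)
    fam_mean = fam_sum / sizes[:, None]
    expanded = np.repeat(fam_mean, sizes, axis=0)
    return CenteredGenotypes(family_mean=expanded, centered=g - expanded,
                             sibship_ids=fids)


# ------------------------------------------------------------ model objects
class GwasResults:
    """Per-variant association results for one model on one phenotype."""

    def __init__(self, table: pd.DataFrame, model: str, phenotype: str,
                 n: int, n_sibships: int, sd_resid: float, covariates: list):
        self.table = table
        self.model = model
        self.phenotype = phenotype
        self.n = n
        self.n_sibships = n_sibships
        self.sd_resid = sd_resid
        self.covariates = covariates

    @property
    def z(self) -> np.ndarray:
        return (self.table["BETA"] / self.table["SE"]).to_numpy()

    def summary(self) -> str:
        t = self.table
        ok = t["SE"].notna()
        lines = [
            f"{self.model} GWAS of {self.phenotype!r}",
            f"  individuals: {self.n}   sibships: {self.n_sibships}",
            f"  variants: {len(t)} ({int((~ok).sum())} flagged)",
            f"  covariates: {', '.join(self.covariates)}",
            f"  residual SD: {self.sd_resid:.4f}",
            f"  median |Z|: {np.nanmedian(np.abs(t['BETA'] / t['SE'])):.3f}",
        ]
        return "\n".join(lines)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")

    @staticmethod
    def read(path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t", na_values="NA")


class _BaseGwas:
    """Shared machinery; see PopulationGwas / WithinSibshipGwas."""

    model_tag = ""

    def __init__(self, cohort: SibshipCohort, phenotype: str,
                 covariates: list[str] | None = None, n_pcs: int = 20,
                 se_type: str = "cluster"):
        if phenotype not in cohort.phenotypes.columns:
            raise KeyError(f"unknown phenotype {phenotype!r}")
        if se_type not in ("cluster", "naive"):
            raise ValueError("se_type must be 'cluster' or 'naive'")
        self.cohort = cohort
        self.phenotype = phenotype
        if covariates is None:
            base = [c for c in ("sex", "age") if c in cohort.samples.columns]
            covariates = base + cohort.pc_columns()[:n_pcs]
        self.covariates = covariates
        self.se_type = se_type
        self._prepare()

    def _prepare(self):
        cohort, y = self.cohort, self.cohort.phenotypes[self.phenotype]
        c = cohort.samples[self.covariates].to_numpy(dtype=np.float64) \
            if self.covariates else np.empty((len(y), 0))
        ok = y.notna().to_numpy() & np.isfinite(c).all(axis=1)
        codes, _ = pd.factorize(cohort.sibship_ids)
        fam_n = np.bincount(codes[ok], minlength=codes.max() + 1)
        ok &= fam_n[codes] >= 2
        idx = np.flatnonzero(ok)
        idx = idx[np.argsort(codes[idx], kind="stable")]
        self._rows = idx
        self._y = y.to_numpy(dtype=np.float64)[idx]
        self._c = np.column_stack([np.ones(len(idx)), c[idx]])
        sub_codes = pd.factorize(codes[idx])[0]
        self._starts = np.flatnonzero(np.r_[True, np.diff(sub_codes) != 0])
        self._sizes = np.diff(np.r_[self._starts, len(idx)])
        self.n = len(idx)
        self.n_sibships = len(self._starts)
        if self.n_sibships < 2:
            raise ValueError("need phenotype data in at least 2 sibships")
        # residualise phenotype on covariates once (FWL)
        q, _ = np.linalg.qr(self._c)
        self._q = q
        self._yr = self._y - q @ (q.T @ self._y)
        self._df_covar = self._c.shape[1]
        self.sd_resid = float(np.std(self._yr, ddof=self._df_covar))

    def _residualise(self, x):
        return x - self._q @ (self._q.T @ x)

    def _cluster_factor(self):
        g = self.n_sibships
        return g / (g - 1.0)

    def _finalise(self, beta, se, extra=None) -> GwasResults:
        cohort = self.cohort
        g = cohort.genotypes[self._rows].astype(np.float64)
        eaf = g.mean(axis=0) / 2.0
        maf = np.minimum(eaf, 1.0 - eaf)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
            p = 2.0 * stats.norm.sf(np.abs(z))
            eff_n = (1.0 / se**2) * self.sd_resid**2 / (2.0 * maf * (1.0 - maf))
        table = pd.DataFrame({
            "SNP": cohort.variants["SNP"].to_numpy(),
            "CHR": cohort.variants["CHR"].to_numpy(),
            "BP": cohort.variants["BP"].to_numpy(),
            "EA": cohort.variants["EA"].to_numpy(),
            "OA": cohort.variants["OA"].to_numpy(),
            "EAF": eaf, "BETA": beta, "SE": se, "P": p,
            "N": self.n, "EFF_N": eff_n, "MODEL": self.model_tag,
        })
        if extra:
            for k, v in extra.items():
                table[k] = v
        table["FLAG"] = np.where(np.isfinite(beta) & np.isfinite(se), "",
                                 "no_variance")
        return GwasResults(table=table, model=self.model_tag,
                           phenotype=self.phenotype, n=self.n,
                           n_sibships=self.n_sibships, sd_resid=self.sd_resid,
                           covariates=self.covariates)


class PopulationGwas(_BaseGwas):
    """Covariate-adjusted regression of the phenotype on raw allele count."""

    model_tag = "population"

    def fit(self, chunk_size: int = 512) -> GwasResults:
        m = self.cohort.n_variants
        beta = np.full(m, np.nan)
        var = np.full(m, np.nan)
        genotypes = self.cohort.genotypes
        for lo in range(0, m, chunk_size):
            hi = min(lo + chunk_size, m)
            g = genotypes[self._rows, lo:hi].astype(np.float64)
            gr = self._residualise(g)
            sxx = np.einsum("ij,ij->j", gr, gr)
            good = sxx > 1e-10
            sxy = gr.T @ self._yr
            b = np.where(good, sxy / np.where(good, sxx, 1.0), np.nan)
            u = self._yr[:, None] - gr * b
            if self.se_type == "cluster":
                scores = np.add.reduceat(gr * u, self._starts, axis=0)
                meat = np.einsum("ij,ij->j", scores, scores)
                v = meat / sxx**2 * self._cluster_factor()
            else:
                dof = self.n - self._df_covar - 1
                sigma2 = np.einsum("ij,ij->j", u, u) / dof
                v = sigma2 / sxx
            beta[lo:hi] = b
            var[lo:hi] = np.where(good, v, np.nan)
        return self._finalise(beta, np.sqrt(var))


class WithinSibshipGwas(_BaseGwas):
    """Regression on the within-sibship genotype deviation G^C with G^F held.

    The G^C coefficient estimates the direct genetic effect free of
    parental-genotype-linked confounding; the G^F coefficient absorbs
    between-family pathways (indirect effects, stratification, assortment).
    """

    model_tag = "within_sibship"

    def fit(self, chunk_size: int = 512) -> GwasResults:
        m = self.cohort.n_variants
        out = {k: np.full(m, np.nan) for k in ("b1", "v1", "b2", "v2")}
        genotypes = self.cohort.genotypes
        sizes, starts = self._sizes, self._starts
        for lo in range(0, m, chunk_size):
            hi = min(lo + chunk_size, m)
            g = genotypes[self._rows, lo:hi].astype(np.float64)
            fam_mean = np.add.reduceat(g, starts, axis=0) / sizes[:, None]
            f = np.repeat(fam_mean, sizes, axis=0)
            gc = g - f            # exact within-family deviations
            gcr = self._residualise(gc)
            fr = self._residualise(f)
            a11 = np.einsum("ij,ij->j", gcr, gcr)
            a12 = np.einsum("ij,ij->j", gcr, fr)
            a22 = np.einsum("ij,ij->j", fr, fr)
            det = a11 * a22 - a12**2
            good = (a11 > 1e-10) & (det > 1e-12)
            safe_det = np.where(good, det, 1.0)
            s1 = gcr.T @ self._yr
            s2 = fr.T @ self._yr
            b1 = (a22 * s1 - a12 * s2) / safe_det
            b2 = (a11 * s2 - a12 * s1) / safe_det
            u = self._yr[:, None] - gcr * b1 - fr * b2
            if self.se_type == "cluster":
                sc1 = np.add.reduceat(gcr * u, starts, axis=0)
                sc2 = np.add.reduceat(fr * u, starts, axis=0)
                m11 = np.einsum("ij,ij->j", sc1, sc1)
                m12 = np.einsum("ij,ij->j", sc1, sc2)
                m22 = np.einsum("ij,ij->j", sc2, sc2)
                cf = self._cluster_factor()
                v1 = (a22**2 * m11 - 2 * a22 * a12 * m12 + a12**2 * m22) \
                    / safe_det**2 * cf
                v2 = (a12**2 * m11 - 2 * a11 * a12 * m12 + a11**2 * m22) \
                    / safe_det**2 * cf
            else:
                dof = self.n - self._df_covar - 2
                sigma2 = np.einsum("ij,ij->j", u, u) / dof
                v1 = sigma2 * a22 / safe_det
                v2 = sigma2 * a11 / safe_det
            for key, val in (("b1", b1), ("v1", v1), ("b2", b2), ("v2", v2)):
                out[key][lo:hi] = np.where(good, val, np.nan)
        return self._finalise(out["b1"], np.sqrt(out["v1"]),
                              extra={"FBETA": out["b2"],
                                     "FSE": np.sqrt(out["v2"])})


def fit_population_model(cohort, phenotype, covariates=None, **kw) -> GwasResults:
    """Functional wrapper over :class:`PopulationGwas`."""
    return PopulationGwas(cohort, phenotype, covariates=covariates, **kw).fit()


def fit_within_sibship_model(cohort, phenotype, covariates=None, **kw) -> GwasResults:
    """Functional wrapper over :class:`WithinSibshipGwas`."""
    return WithinSibshipGwas(cohort, phenotype, covariates=covariates, **kw).fit()
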