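"""In-memory container and tab-separated I/O for sibship cohorts.

A cohort couples a hard-call genotype matrix (individuals x variants, allele
counts in {0, 1, 2}) with a sample table (sibship membership, subpopulation,
covariates, phenotypes) and a variant table (identifier, position, alleles,
frequency). Latent parental genotypes and a truth table are carried along when
the cohort was simulated, so estimators can be validated against the generative
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: columns every variant table carries; IDs follow the chr:bp:type convention
VARIANT_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "MAF", "INFO"]


def variant_id(chrom: int, bp: int, vtype: str = "SNP") -> str:
    """Harmonized variant identifier: chromosome, base pair, polymorphism type."""
    return f"{chrom}:{bp}:{vtype}"


@dataclass
class SibshipCohort:
    genotypes: np.ndarray              # (n_individuals, n_variants) int8
    samples: pd.DataFrame              # IID, FID, father, mother, subpop, sex, age, PC*
    variants: pd.DataFrame             # VARIANT_COLUMNS (+ simulation truth columns)
    phenotypes: pd.DataFrame = None    # one column per phenotype, aligned to samples
    parent_genotypes: dict = None      # {"father": array, "mother": array} per sibship
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.phenotypes is None:
            self.phenotypes = pd.DataFrame(index=self.samples.index)
        g = np.asarray(self.genotypes)
        if g.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        if g.shape[0] != len(self.samples):
            raise ValueError("genotype rows must match sample table")
        if g.shape[1] != len(self.variants):
            raise ValueError("genotype columns must match variant table")
        if g.size and (g.min() < 0 or g.max() > 2):
            raise ValueError("allele counts must lie in {0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sibship_ids(self) -> np.ndarray:
        return self.samples["FID"].to_numpy()

    def sibship_sizes(self) -> pd.Series:
        return self.samples.groupby("FID").size()

    def pc_columns(self) -> list[str]:
        return [c for c in self.samples.columns if c.startswith("PC")]

    def subset(self, row_mask) -> "SibshipCohort":
        """Row-subset the cohort (parental genotypes are kept per sibship)."""
        row_mask = np.asarray(row_mask)
        idx = np.flatnonzero(row_mask) if row_mask.dtype == bool else row_mask
        return SibshipCohort(
            genotypes=self.genotypes[idx],
            samples=self.samples.iloc[idx].reset_index(drop=True),
            variants=self.variants,
            phenotypes=self.phenotypes.iloc[idx].reset_index(drop=True),
            parent_genotypes=self.parent_genotypes,
            truth=self.truth,
        )

    # ------------------------------------------------------------------ I/O
    def write(self, prefix) -> None:
        """Write pedigree, genotype and phenotype/covariate tables as TSV."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        ped_cols = [c for c in ["IID", "FID", "father", "mother", "subpop"]
                    if c in self.samples.columns]
        self.samples[ped_cols].to_csv(f"{prefix}.ped.tsv", sep="\t", index=False)
        geno = pd.DataFrame(self.genotypes, columns=self.variants["SNP"])
        geno.insert(0, "IID", self.samples["IID"].to_numpy())
        geno.to_csv(f"{prefix}.geno.tsv", sep="\t", index=False)
        covar_cols = [c for c in self.samples.columns if c not in
                      ("FID", "father", "mother", "subpop")]
        pheno = pd.concat(
            [self.samples[covar_cols], self.phenotypes.reset_index(drop=True)], axis=1
        )
        pheno.to_csv(f"{prefix}.pheno.tsv", sep="\t", index=False)
        self.variants.to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, prefix) -> "SibshipCohort":
        prefix = Path(prefix)
        ped = pd.read_csv(f"{prefix}.ped.tsv", sep="\t")
        geno = pd.read_csv(f"{prefix}.geno.tsv", sep="\t")
        pheno = pd.read_csv(f"{prefix}.pheno.tsv", sep="\t")
        variants = pd.read_csv(f"{prefix}.variants.tsv", sep="\t")
        g = geno.drop(columns="IID").to_numpy(dtype=np.int8)
        covar = pheno.drop(columns="IID")
        samples = pd.concat([ped.reset_index(drop=True), covar], axis=1)
        known = {"sex", "age"} | {c for c in samples.columns if c.startswith("PC")}
        pheno_cols = [c for c in covar.columns if c not in known]
        phenotypes = samples[pheno_cols].copy()
        samples = samples.drop(columns=pheno_cols)
        return cls(genotypes=g, samples=samples, variants=variants,
                   phenotypes=phenotypes)
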