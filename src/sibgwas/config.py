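"""Configuration objects for the family-cohort and summary-statistic simulators.

All randomness in the package flows from a single integer seed through
:class:`numpy.random.SeedSequence` spawning, so that every operation draws
from a documented substream and whole scenarios are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml


@dataclass
class StratConfig:
    """Two-subpopulation stratification structure.

    freq_divergence : total allele-frequency difference |p1 - p2| applied per
        variant as +/- freq_divergence/2 around the base MAF (random sign).
    pheno_offset : phenotype mean difference (in phenotype SD units) added to
        subpopulation 1.
    pc_leakage_sd : SD of the noise added to the subpopulation indicator when
        simulating principal components; 0 gives PCs that perfectly tag the
        structure, larger values emulate PCs that only partially capture
        fine-scale structure.
    """

    freq_divergence: float = 0.0
    pheno_offset: float = 0.0
    pc_leakage_sd: float = 0.5

    def validate(self) -> None:
        if self.freq_divergence < 0:
            raise ValueError("freq_divergence must be nonnegative")
        if self.pc_leakage_sd < 0:
            raise ValueError("pc_leakage_sd must be nonnegative")


@dataclass
class SimulationConfig:
    """Generative knobs for a sibship cohort.

    Phenotype model per individual (before adding noise to reach unit
    variance):

        y = sum_causal beta_direct * G_own
          + eta_parental * (G_mother + G_father)
          + eta_sibling  * sum_sibs G_sib
          + pheno_offset * 1{subpop 1}
          + shared_env (per sibship, or per linked sibship group)
    """

    n_sibships: int = 1000
    sibs_per_family: int | Mapping[int, float] = 2
    n_variants: int = 100
    n_causal: int | None = None  # default: all variants causal
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_direct: float = 0.0
    eta_parental: float = 0.0
    eta_sibling: float = 0.0
    am_corr: float = 0.0
    strat: StratConfig = field(default_factory=StratConfig)
    shared_env_var: float = 0.0
    cryptic_relatedness_frac: float = 0.0
    n_pcs: int = 20
    pcs_from_genotypes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.strat, dict):
            self.strat = StratConfig(**self.strat)
        if isinstance(self.maf_range, list):
            self.maf_range = tuple(self.maf_range)
        self.validate()

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range must lie within (0, 1)")
        if self.n_sibships <= 0 or self.n_variants <= 0:
            raise ValueError("n_sibships and n_variants must be positive")
        if not (0 <= self.am_corr < 1):
            raise ValueError("am_corr must be in [0, 1)")
        if self.shared_env_var < 0:
            raise ValueError("shared_env_var must be nonnegative")
        if not (0 <= self.cryptic_relatedness_frac <= 1):
            raise ValueError("cryptic_relatedness_frac must be in [0, 1]")
        if isinstance(self.sibs_per_family, int):
            if self.sibs_per_family < 2:
                raise ValueError("sibships need at least 2 siblings")
        else:
            if any(int(k) < 2 for k in self.sibs_per_family):
                raise ValueError("sibship sizes must all be >= 2")
        self.strat.validate()

    @property
    def n_causal_effective(self) -> int:
        return self.n_variants if self.n_causal is None else self.n_causal

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


@dataclass
class LdscSimConfig:
    """Generative model for GWAS summary statistics under LD score regression.

    Z scores are drawn as N(0, sqrt(N * h2 * l_j / M + N * a + 1)) so that
    chi2 = Z^2 has mean N h2 l_j / M + N a + 1; ``a`` is the per-individual
    confounding inflation and ``l_j`` the LD score of variant j.
    """

    M: int = 20000
    N: float = 20000.0
    h2_true: float = 0.3
    a_confound: float = 0.0
    mean_ldscore: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 <= self.h2_true <= 1):
            raise ValueError("h2_true must be in [0, 1]")
        if self.a_confound < 0:
            raise ValueError("a_confound must be nonnegative")
        if self.M <= 0 or self.N <= 0:
            raise ValueError("M and N must be positive")
        if self.mean_ldscore < 1:
            raise ValueError("mean LD score must be >= 1")
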