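import numpy as np
import pandas as pd
import pytest

import sibgwas as sg


@pytest.fixture(scope="session")
def parental_cohort():
    """Cohort with equal direct and parental indirect effects (beta=eta=0.1)."""
    cfg = sg.SimulationConfig(n_sibships=5000, n_variants=30, n_causal=30,
                              beta_direct=0.1, eta_parental=0.1, seed=101)
    return sg.simulate_cohort(cfg), cfg


@pytest.fixture
def tiny_cohort():
    """Hand-buildable cohort: 4 sibships of 2, 3 variants, no covariates."""
    rng = np.random.default_rng(0)
    genotypes = rng.integers(0, 3, size=(8, 3)).astype(np.int8)
    samples = pd.DataFrame({
        "IID": [f"i{k}" for k in range(8)],
        "FID": np.repeat([f"F{k}" for k in range(4)], 2),
        "subpop": 0,
        "sex": rng.integers(0, 2, 8),
        "age": rng.normal(50, 5, 8),
    })
    variants = pd.DataFrame({
        "SNP": [f"1:{i}:SNP" for i in (100, 200, 300)],
        "CHR": 1, "BP": [100, 200, 300], "EA": "A", "OA": "G",
        "MAF": 0.3, "INFO": 1.0,
    })
    pheno = pd.DataFrame({"trait": rng.normal(size=8)})
    return sg.SibshipCohort(genotypes=genotypes, samples=samples,
                            variants=variants, phenotypes=pheno)


def summary_shrinkage_draw(rng, m=30, true_ratio=0.5, se_p=0.01, se_w=0.015,
                           w_mean=0.1, w_sd=0.02):
    """Summary-level draw of aligned population / within-sibship betas."""
    w = rng.normal(w_mean, w_sd, m)
    beta_p = w + rng.normal(0, se_p, m)
    beta_w = true_ratio * w + rng.normal(0, se_w, m)
    return (beta_p, np.full(m, se_p), beta_w, np.full(m, se_w), w)
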