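import numpy as np
import pandas as pd
import pytest

from polytrans import frames
from polytrans.genio import (
    GenotypeMatrix,
    Pedigree,
    PhenotypeTable,
    SnpPanel,
    WeightTable,
)
from polytrans.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def toy_genotypes():
    panel = SnpPanel(["rs1", "rs2", "rs3"], ["A", "C", "G"],
                     allele_freq=np.array([0.5, 0.3, 0.8]))
    dosage = np.array(
        [[0.0, 1.0, 2.0],
         [1.0, 1.0, 1.0],
         [2.0, 0.0, 0.0],
         [1.0, 2.0, 1.0]]
    )
    return GenotypeMatrix(["s1", "s2", "s3", "s4"], panel, dosage)


@pytest.fixture(scope="session")
def toy_weights():
    return WeightTable(
        pd.DataFrame(
            {"snp_id": ["rs1", "rs2", "rs3"],
             "effect_allele": ["A", "C", "G"],
             "weight": [0.5, -0.25, 0.1]}
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort reused across modules (no burn-in niceties needed)."""
    cfg = SimConfig(n_families=800, m_snps=150, n_burnin=4, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_frame(small_cohort):
    b = small_cohort
    return frames.cohort_frame(
        b.genotypes, b.pedigree, b.phenotypes, b.noisy_weights
    )


@pytest.fixture(scope="session")
def calibrated_cohort():
    """Larger cohort at the default (survey-calibrated) configuration."""
    cfg = SimConfig(n_families=5000, m_snps=300, n_burnin=8, seed=3)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def calibrated_frame(calibrated_cohort):
    b = calibrated_cohort
    return frames.cohort_frame(
        b.genotypes, b.pedigree, b.phenotypes, b.noisy_weights
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def clustered_testdata(rng, n_families=40, k=3, beta=(1.0, 0.5, -0.25)):
    """Small clustered regression dataset with known coefficients."""
    rows = []
    for f in range(n_families):
        u = rng.normal()
        for _ in range(k):
            x1, x2 = rng.normal(), rng.normal()
            y = beta[0] + beta[1] * x1 + beta[2] * x2 + u + rng.normal()
            rows.append((f"fam{f}", x1, x2, y))
    return pd.DataFrame(rows, columns=["family_id", "x1", "x2", "y"])
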