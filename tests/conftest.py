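import numpy as np
import pytest

from vntrstat import SimConfig, fit_prediction_weights, generate_study
from vntrstat.panel import TagPanel


def random_panel(seed, n=50, m=3, with_vntr=True):
    """Small dense panel with random dosages, no structure."""
    rng = np.random.default_rng(seed)
    geno = rng.integers(0, 3, size=(n, m)).astype(float)
    # guarantee polymorphism
    for j in range(m):
        if geno[:, j].std() == 0:
            geno[0, j] = (geno[0, j] + 1) % 3
    vntr = rng.integers(0, 3, size=n).astype(float) if with_vntr else None
    return TagPanel(
        sample_ids=[f"s{i}" for i in range(n)],
        snp_ids=[f"snp{j}" for j in range(m)],
        effect_alleles=["A"] * m,
        other_alleles=["G"] * m,
        genotypes=geno,
        vntr_dosage=vntr,
    )


@pytest.fixture(scope="session")
def study():
    """One synthetic study reused across read-only tests."""
    return generate_study(SimConfig(seed=101, alpha=0.1, n_gwas=10_000))


@pytest.fixture(scope="session")
def study_model(study):
    return fit_prediction_weights(study.train_panel)
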