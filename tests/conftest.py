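import numpy as np
import pandas as pd
import pytest

from pdprs.sim import make_design, simulate_all


@pytest.fixture(scope="session")
def tiny_design():
    """Desk-scale design: 47 blocks x 20 SNPs, defaults otherwise."""
    return make_design(seed=42, snps_per_block=20)


@pytest.fixture(scope="session")
def tiny_sim(tiny_design):
    """One small end-to-end replicate (1,500 individuals)."""
    return simulate_all(tiny_design, 1_500)


@pytest.fixture()
def snp_manifest():
    return pd.DataFrame({
        "snp": ["rs1", "rs2", "rs3", "rs4", "rs5"],
        "chrom": ["1", "1", "1", "1", "1"],
        "pos": [10, 50, 101, 150, 250],
        "a1": ["A", "C", "G", "T", "A"],
        "a2": ["G", "T", "A", "C", "C"],
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
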