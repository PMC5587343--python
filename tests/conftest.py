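import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from epidrift.simulate import SimConfig, simulate_dataset
from epidrift.types import BetaMatrix, ExprMatrix, ProbeAnnotation, SampleTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

SMALL_CFG = SimConfig(n_genes=400, n_drift_genes=6, n_aneuploid_samples=1, seed=7)
NOISE_FREE_CFG = SimConfig(
    n_genes=300,
    n_drift_genes=5,
    beta_noise_sd=0.0,
    expr_noise_sd=0.0,
    n_aneuploid_samples=0,
    unexpressed_gene_fraction=0.0,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SMALL_CFG


@pytest.fixture(scope="session")
def small_sim():
    return simulate_dataset(SMALL_CFG)


@pytest.fixture(scope="session")
def noise_free_cfg():
    return NOISE_FREE_CFG


@pytest.fixture(scope="session")
def noise_free_sim():
    return simulate_dataset(NOISE_FREE_CFG)


def make_samples(passages, qc_pass=None, sex=None):
    """Handcrafted sample table: one line per sample."""
    n = len(passages)
    df = pd.DataFrame(
        {
            "cell_line": [f"line{i}" for i in range(n)],
            "passage": list(passages),
            "sex": sex if sex is not None else ["female"] * n,
            "cell_type": ["hESC"] * n,
            "qc_pass": qc_pass if qc_pass is not None else [True] * n,
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )
    return SampleTable(df)


def make_annotation(rows):
    """rows: list of (probe_id, gene, chromosome, position, island, platform)."""
    df = pd.DataFrame(
        rows,
        columns=["probe_id", "gene", "chromosome", "position", "in_cpg_island", "platform"],
    ).set_index("probe_id")
    return ProbeAnnotation(df)
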