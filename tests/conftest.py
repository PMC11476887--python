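import numpy as np
import pandas as pd
import pytest

from exmr import synthio


@pytest.fixture(scope="session")
def small_cfg() -> synthio.SimConfig:
    return synthio.SimConfig(seed=42, n_genes=200, n_mirnas=60,
                             de_fraction=0.2, demir_fraction=0.25,
                             lfc_magnitude=2.0, n_blocks=4, snps_per_block=6,
                             n_exp=600, n_out=3000)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return synthio.simulate_study(small_cfg, n_mr_genes=4, n_causal=2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_de_table(lfcs: dict[str, float], padj: float = 0.01) -> pd.DataFrame:
    """Tiny DE result table with the given significant log2 fold changes."""
    return pd.DataFrame({
        "feature": list(lfcs),
        "base_mean": 100.0,
        "log2fc": list(lfcs.values()),
        "p": padj / 2,
        "padj": padj,
        "all_zero": False,
    })
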