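import numpy as np
import pandas as pd
import pytest

from cfdonor.blocks import build_blocks
from cfdonor.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture(scope="session")
def tiny_map():
    """Uniform 1 cM/Mb map on two small chromosomes."""
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2", "chr2"],
            "pos": [1, 10_000_000, 1, 6_000_000],
            "cm": [0.0, 10.0, 0.0, 6.0],
        }
    )


def make_snps(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "allele_a": "A",
            "allele_b": "B",
        }
    )


@pytest.fixture(scope="session")
def small_sibling_sim():
    """50K-SNP sibling mixture at d = 0.10 (shared across recovery tests)."""
    cfg = SimulationConfig(
        n_snps=50_000, d_true=0.10, coverage=1.75,
        p_ibd_1=0.5, p_ibd_2=0.5, seed=1234,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_unrelated_sim():
    """50K-SNP unrelated mixture at d = 0.05, 1x coverage."""
    cfg = SimulationConfig(n_snps=50_000, d_true=0.05, coverage=1.0, seed=4321)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def toy_blocks(tiny_map):
    """Block partition over 200 SNPs on chr1 (10 cM) and 60 on chr2 (6 cM)."""
    pos1 = np.linspace(1, 9_999_999, 200).astype(int)
    pos2 = np.linspace(1, 5_999_999, 60).astype(int)
    snps = pd.concat(
        [make_snps(pos1, "chr1"), make_snps(pos2, "chr2")], ignore_index=True
    )
    return snps, build_blocks(tiny_map, snps, target_cm=2.0)
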