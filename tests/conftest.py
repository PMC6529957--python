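import numpy as np
import pandas as pd
import pytest

from m6atrio import SimulationConfig


@pytest.fixture
def gwas_frame():
    """Six-SNP canonical GWAS frame spanning the MAF bins."""
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(1, 7)],
        "chrom": ["1", "1", "2", "2", "3", "3"],
        "pos": [100, 200, 300, 400, 500, 600],
        "effect_allele": list("ACGTAC"),
        "other_allele": list("GTACGT"),
        "eaf": [0.3736, 0.9, 0.05, 0.45, 0.2, 0.12],
        "beta": [0.1, -0.2, 0.3, 0.0, 0.5, -0.1],
        "se": [0.05, 0.04, 0.2, 0.1, 0.3, 0.08],
        "p": [0.04, 0.5, 0.01, 0.9, 0.06, 0.05],
        "trait": "AIS",
    }).assign(maf=lambda d: np.minimum(d.eaf, 1 - d.eaf))


@pytest.fixture
def m6a_sites():
    return pd.DataFrame({
        "m6a_id": ["m6A_ID_132331", "m6A_ID_2", "m6A_ID_3"],
        "snp": ["rs1", "rs3", "rs3"],
        "chrom": ["1", "2", "2"],
        "site_pos": [120, 290, 310],
        "confidence": ["high", "low", "medium"],
        "effect": ["Loss", "Gain", "Gain"],
    })


@pytest.fixture
def small_cfg():
    return SimulationConfig(n_snps=2000, n_genes=100, seed=11)


def write_tsv(path, df):
    df.to_csv(path, sep="\t", index=False)
    return path
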