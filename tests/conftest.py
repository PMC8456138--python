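import numpy as np
import pandas as pd
import pytest

from asexpress import exprnorm, simdata


@pytest.fixture
def small_config():
    """Reduced-size simulation for fast structural tests."""
    return simdata.SimulationConfig(n_genes=400, seed=7, n_core_asex_genes=10,
                                    n_private_asex_genes=5)


@pytest.fixture
def small_dataset(small_config):
    return simdata.simulate_dataset(small_config)


@pytest.fixture
def normalized_default():
    """One default-size simulated dataset taken through RPKM + quantile
    normalization; shared by the LDA and shift tests."""
    cfg = simdata.SimulationConfig(seed=3)
    counts, meta, gene_meta, truth = simdata.simulate_dataset(cfg)
    keep = exprnorm.filter_transcripts(gene_meta["length_bp"], 500).intersection(counts.index)
    rpkm = exprnorm.compute_rpkm(counts.loc[keep], gene_meta["length_bp"].loc[keep])
    norm = exprnorm.quantile_normalize(rpkm, exprnorm.tissue_groups(meta))
    return counts.loc[keep], meta, gene_meta.loc[keep], truth, norm


def nb_counts(rng, mu, alpha, n_cols, prefix):
    cols = {}
    for i in range(n_cols):
        if alpha == 0:
            cols[f"{prefix}{i+1}"] = rng.poisson(mu)
        else:
            r = 1.0 / alpha
            cols[f"{prefix}{i+1}"] = rng.negative_binomial(r, r / (r + mu))
    return cols


@pytest.fixture
def spiked_counts():
    """3v3 NB counts with 10% of genes carrying a true |log2fc| = 2."""
    rng = np.random.default_rng(11)
    g = 2000
    mu = np.exp2(rng.normal(6, 1.5, g))
    spiked = np.zeros(g, bool)
    spiked[rng.choice(g, g // 10, replace=False)] = True
    lfc = np.where(spiked, rng.choice([2.0, -2.0], g), 0.0)
    cols = nb_counts(rng, mu, 0.05, 3, "A") | nb_counts(rng, mu * 2.0**lfc, 0.05, 3, "B")
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(g)])
    return counts, spiked, lfc
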