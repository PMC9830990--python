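import numpy as np
import pandas as pd
import pytest

from evoexpr.datamodel import CountDataset, SampleInfo
from evoexpr.normalize import filter_genes, logcpm_matrix, tmm_factors
from evoexpr.simulate import SimulationConfig, simulate_dataset


def make_dataset(counts, regimes=None, lines=None, sexes=None, tissues=None,
                 gene_ids=None, sample_ids=None):
    """Hand-build a CountDataset from a small matrix and factor vectors."""
    counts = np.asarray(counts)
    G, S = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(G)]
    sample_ids = sample_ids or [f"s{j}" for j in range(S)]
    regimes = regimes or ["E"] * (S // 2) + ["L"] * (S - S // 2)
    lines = lines or list(range(1, S + 1))
    sexes = sexes or ["F"] * S
    tissues = tissues or ["abdomen"] * S
    design = {
        s: SampleInfo(regime=r, line=l, sex=x, tissue=t)
        for s, r, l, x, t in zip(sample_ids, regimes, lines, sexes, tissues)
    }
    return CountDataset(gene_ids=gene_ids, sample_ids=sample_ids,
                        counts=counts, design=design)


def write_counts_files(tmp_path, counts, design_rows, gene_ids=None,
                       sample_ids=None):
    counts = np.asarray(counts)
    G, S = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(G)]
    sample_ids = sample_ids or [f"s{j}" for j in range(S)]
    cdf = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    cdf.index.name = "gene"
    counts_path = tmp_path / "counts.tsv"
    cdf.to_csv(counts_path, sep="\t")
    ddf = pd.DataFrame(design_rows,
                       columns=["sample", "regime", "line", "sex", "tissue"])
    design_path = tmp_path / "design.tsv"
    ddf.to_csv(design_path, sep="\t", index=False)
    return counts_path, design_path


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated dataset shared by read-only tests."""
    cfg = SimulationConfig(n_genes=600, tissues=("abdomen",), rng_seed=42,
                           frac_regime_de=0.1, frac_sex_biased={"abdomen": 0.2})
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_norm(small_sim):
    dataset, _ = small_sim
    sub = filter_genes(dataset)
    return sub, logcpm_matrix(sub, tmm_factors(sub))
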