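import numpy as np
import pytest

from actin.chemgraph import parse_smiles
from actin.genespace import GeneEmbeddingTable
from actin.model import CellLineModel, ModelConfig
from actin.synthdata import PlantedEffect, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_model():
    """A small randomly initialised model (d=32, 2 blocks, 2 stages)."""
    return CellLineModel("TINY", ModelConfig.reduced(d=32, d_k=8, heads=4,
                                                     n_blocks=2, gene_dim=16), seed=7)


@pytest.fixture(scope="session")
def small_molecules():
    smiles = ["C", "CC", "CCO", "c1ccccc1", "CCOS(C)CC", "CC(N)C(=O)O",
              "CCSCC", "ClCCBr", "CC(C)CP"]
    return [parse_smiles(s) for s in smiles]


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 drugs x 8 genes with a planted S effect and no noise."""
    cfg = SynthConfig(
        n_drugs=12, n_genes=8,
        effects=[PlantedEffect("S", frozenset({0, 1}), beta=2.0, direction=+1)],
        noise_sd=0.0, seed=11, min_atoms=4, max_atoms=8,
    )
    molecules, records = generate_dataset(cfg)
    return cfg, molecules, records


@pytest.fixture(scope="session")
def tiny_gene_table():
    rng = np.random.default_rng(5)
    ids = tuple(f"g{i + 1:04d}" for i in range(8))
    return GeneEmbeddingTable(ids, rng.normal(size=(8, 16)))
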