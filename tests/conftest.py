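import numpy as np
import pandas as pd
import pytest

from omicsbn import (
    LayerDefinition,
    OmicsDataset,
    default_hyperparameters,
    enumerate_candidate_edges,
)
from omicsbn.bge import ScoreCache
from omicsbn.datasets import GE, Node


@pytest.fixture(scope="session")
def three_gene_ds():
    """Fixed 3-gene, 6-sample expression dataset (seeded once)."""
    rng = np.random.default_rng(42)
    x = rng.standard_normal((6, 3))
    x[:, 1] += 0.8 * x[:, 0]
    x[:, 2] += 0.6 * x[:, 1]
    ge = pd.DataFrame(x, index=[f"S{i}" for i in range(6)],
                      columns=["A", "B", "C"])
    return OmicsDataset(ge=ge).validate()


@pytest.fixture(scope="session")
def three_gene_setup(three_gene_ds):
    ds = three_gene_ds
    layers = LayerDefinition(((GE, 3),))
    cand = enumerate_candidate_edges(ds, layers)
    hp = default_hyperparameters(ds)
    cache = ScoreCache(ds, hp)
    return ds, layers, cand, hp, cache


def write_tsv(path, df):
    df.to_csv(path, sep="\t")
    return str(path)
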