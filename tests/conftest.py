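import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from spatialsom import ExpressionMatrix, SOMConfig, SyntheticDesign, generate_embryo

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_design():
    return SyntheticDesign()


@pytest.fixture(scope="session")
def embryo(default_design):
    """Default synthetic embryo: (ExpressionMatrix, annotation)."""
    return generate_embryo(default_design)


@pytest.fixture(scope="session")
def discriminator_genes(default_design):
    return [d.gene_id for d in default_design.discriminators]


@pytest.fixture()
def tiny_matrix():
    """3 genes x 4 samples raw FPKM matrix with hand-set values."""
    frame = pd.DataFrame(
        [[2.0, 3.0, 0.0, 5.0], [0.0, 0.0, 0.0, 0.0], [9.0, 99.0, 0.0, 9.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(frame)


@pytest.fixture()
def fast_cfg():
    """Short deterministic-ish config for structural tests."""
    return SOMConfig(n_steps=20, seed=0)


def make_matrix(values, gene_ids=None, sample_ids=None, transformed=False):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), transformed
    )
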