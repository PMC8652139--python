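import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from perturbsem import ExpressionMatrix, GeneSignature, OrthologMap


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, hand-checkable values."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 0.0, 1.0], [-1.0, 2.0, -3.0, 4.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(df, level="gene")


@pytest.fixture
def random_gene_matrix(rng):
    n_genes, n_samples = 40, 12
    df = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(df, level="gene")


@pytest.fixture
def simple_signature():
    return GeneSignature(frozenset({"Ua", "Ub", "Uc"}), frozenset({"Da", "Db"}), species="mouse")


@pytest.fixture
def identity_map():
    return OrthologMap.identity([f"G{i:03d}" for i in range(40)])
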