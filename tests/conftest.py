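import numpy as np
import pandas as pd
import pytest

from diffregnet.dataio import ExpressionDataset
from diffregnet.grn import GRN


def make_dataset(matrix, genes=None, samples=None, labels=None) -> ExpressionDataset:
    """Build a small ExpressionDataset from a 2-D array-like."""
    mat = np.asarray(matrix, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(mat.shape[0])]
    samples = samples or [f"s{i + 1}" for i in range(mat.shape[1])]
    if labels is None:
        half = mat.shape[1] // 2
        labels = ["A"] * half + ["B"] * (mat.shape[1] - half)
    return ExpressionDataset(
        values=pd.DataFrame(mat, index=genes, columns=samples),
        condition_of=pd.Series(labels, index=samples, dtype=object),
    )


def random_grn_pair(rng, n_genes=20, n_links=30, conditions=("A", "B")):
    """Two random GRNs over a shared TF/target universe, with partial overlap."""
    tfs = [f"t{i}" for i in range(max(2, n_genes // 4))]
    targets = [f"g{i}" for i in range(n_genes)]
    n_links = min(n_links, len(tfs) * len(targets))
    def one(cond):
        links = {}
        while len(links) < n_links:
            tf = tfs[rng.integers(len(tfs))]
            tg = targets[rng.integers(len(targets))]
            links[(tf, tg)] = float(rng.normal()) or 0.1
        return GRN(condition=cond, links=links)
    return one(conditions[0]), one(conditions[1])


@pytest.fixture
def two_block_dataset():
    """10 genes x 12 samples with distinct group means; 6 samples per condition."""
    rng = np.random.default_rng(42)
    mat = rng.standard_normal((10, 12))
    mat[:5, 6:] += 3.0
    return make_dataset(mat)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
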