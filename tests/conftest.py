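import numpy as np
import pytest

from mtann.containers import LabeledDataset, ReferenceSubset
from mtann.ensemble import PredictionStack


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_dataset(rng, n_cells=12, n_genes=8, labels=None, stage=None):
    matrix = rng.poisson(3.0, size=(n_cells, n_genes)).astype(float) + 0.0
    matrix[0, :] += 1  # guard against an all-zero first cell
    ds = LabeledDataset(
        matrix=matrix,
        genes=[f"g{j}" for j in range(n_genes)],
        cells=[f"c{i}" for i in range(n_cells)],
        labels=None if labels is None else np.asarray(labels, dtype=object),
    )
    return ds


@pytest.fixture
def small_dataset(rng):
    labels = ["A"] * 6 + ["B"] * 6
    return make_dataset(rng, n_cells=12, n_genes=8, labels=labels)


def random_stack(rng, n_subsets=6, n_cells=20, n_classes=4, counts=None):
    """A synthetic prediction stack with Dirichlet probability rows."""
    probs = rng.dirichlet(np.ones(n_classes), size=(n_subsets, n_cells))
    vocab = [f"T{k}" for k in range(n_classes)]
    if counts is None:
        counts = rng.integers(1, n_subsets + 1, size=n_classes)
    subsets = []
    for s in range(n_subsets):
        subsets.append(None)
    return PredictionStack(
        probs=probs,
        hard=np.argmax(probs, axis=2),
        counts=np.asarray(counts, dtype=np.int64),
        vocabulary=vocab,
        subset_names=[f"s{j}" for j in range(n_subsets)],
    )


@pytest.fixture
def stack(rng):
    return random_stack(rng)
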