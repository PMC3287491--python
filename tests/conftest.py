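import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracle.py

from rfaselect import ExpressionDataset


def make_dataset(values, labels, gene_ids=None, sample_ids=None,
                 class_names=("A", "B")) -> ExpressionDataset:
    """Build a dataset from a genes × samples array and 0/1 labels."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    labels = np.asarray(labels, dtype=int)
    g, s = values.shape
    return ExpressionDataset(
        gene_ids=gene_ids or [f"g{i}" for i in range(g)],
        sample_ids=sample_ids or [f"s{i}" for i in range(s)],
        values=values,
        labels=labels,
        class_names=class_names,
    )


@pytest.fixture
def tiny_dataset():
    """3 genes × 4 samples; g0 separates the classes perfectly."""
    return make_dataset(
        [[1.0, 1.1, 5.0, 5.2],
         [3.0, 3.4, 3.1, 3.3],
         [2.0, 7.0, 2.5, 6.5]],
        [0, 0, 1, 1],
    )


def random_dataset(rng, n_genes, n_per_class, informative=0, effect=2.0):
    """Gaussian dataset; the first `informative` genes get a class shift."""
    s = 2 * n_per_class
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    values = rng.standard_normal((n_genes, s))
    values[:informative, labels == 1] += effect
    return make_dataset(values, labels)
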