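import numpy as np
import pytest

from sctemporal.io import CellMetadata, ExpressionMatrix, TimepointDataset


def make_separable_pair(
    n_per_class: int = 200,
    n_genes: int = 100,
    n_marker: int = 20,
    shift: float = 6.0,
    seed: int = 0,
):
    """Two populations with disjoint marker blocks; returns (t0, t1) datasets.

    Both timepoints are drawn from the same generative law, so a correct
    classifier trained on t0 should transfer to t1 nearly perfectly.
    """
    rng = np.random.default_rng(seed)
    base = rng.gamma(2.0, 1.0, size=n_genes) + 0.2

    def draw(tp):
        cols, labels = [], []
        for cls, block in (("B", slice(0, n_marker)), ("T", slice(n_marker, 2 * n_marker))):
            mu = base.copy()
            mu[block] *= shift
            lam = np.tile(mu[:, None], (1, n_per_class))
            cols.append(rng.poisson(lam))
            labels.extend([cls] * n_per_class)
        values = np.concatenate(cols, axis=1)
        order = rng.permutation(values.shape[1])
        values = values[:, order]
        labels = [labels[i] for i in order]
        ids = [f"{tp}_c{i}" for i in range(values.shape[1])]
        meta = CellMetadata(ids, timepoint=[tp] * len(ids), labels=labels)
        genes = [f"g{i}" for i in range(n_genes)]
        return TimepointDataset(ExpressionMatrix(values, genes, ids), meta)

    return draw("t0"), draw("t1")


@pytest.fixture(scope="session")
def separable_pair():
    return make_separable_pair()


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(42)
    values = rng.poisson(2.0, size=(30, 12))
    return ExpressionMatrix(
        values, [f"g{i}" for i in range(30)], [f"c{i}" for i in range(12)]
    )
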