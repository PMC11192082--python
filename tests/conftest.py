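import numpy as np
import pytest

from fibroharmony.datatypes import labels_from_obs
from fibroharmony.syndata import SimConfig, generate_multibatch_counts


@pytest.fixture(scope="session")
def small_sim():
    """Default-world simulation: 3 populations, 2 batches, planted markers."""
    cfg = SimConfig(
        n_genes=1000,
        n_cells_per_batch=[250, 250],
        n_populations=3,
        marker_spec=[["pop0", 15, 2.0], ["pop1", 15, 2.0]],
        seed=11,
    )
    adata, emb, truth = generate_multibatch_counts(cfg)
    return cfg, adata, emb, truth


@pytest.fixture(scope="session")
def small_labels(small_sim):
    _, adata, _, _ = small_sim
    return labels_from_obs(adata, "population")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def separated_blobs(n_per=60, d=5, sep=12.0, n_classes=2, seed=0):
    """Well-separated Gaussian blobs with string labels."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        centre = np.zeros(d)
        centre[c % d] = sep * (1 + c // d)
        X.append(rng.normal(0, 1, size=(n_per, d)) + centre)
        y += [f"state{c}"] * n_per
    return np.vstack(X), np.asarray(y, dtype=object)
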