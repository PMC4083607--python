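import numpy as np
import pytest

from cbep.synthdata import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Four short annotated synthetic antigens with profiles and coordinates."""
    cfg = GeneratorConfig(
        n_antigens=4, chain_length=(60, 100), epitopes_per_antigen=(1, 2)
    )
    return generate_dataset(cfg, seed=5)


@pytest.fixture()
def rng():
    return np.random.RandomState(0)


@pytest.fixture(scope="session")
def blobs():
    """Imbalanced, partially overlapping 2D two-class data (train and test)."""
    r = np.random.RandomState(7)

    def draw(n_neg, n_pos):
        X = np.vstack(
            [r.normal(0.0, 1.0, size=(n_neg, 2)), r.normal(1.6, 1.0, size=(n_pos, 2))]
        )
        y = np.concatenate([np.zeros(n_neg, dtype=int), np.ones(n_pos, dtype=int)])
        perm = r.permutation(len(y))
        return X[perm], y[perm]

    return draw(470, 30), draw(470, 30)
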