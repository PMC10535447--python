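import numpy as np
import pytest

import acps_assf as aa


@pytest.fixture(scope="session")
def bundled_table() -> aa.IndexTable:
    return aa.IndexTable.bundled()


@pytest.fixture(scope="session")
def small_dataset() -> aa.LabeledDataset:
    """40 peptides, strongly composition-separable classes."""
    return aa.generate_synthetic_dataset(
        n_pos=20, n_neg=20, length_range=(10, 30), class_bias=0.9, seed=11
    )


@pytest.fixture(scope="session")
def fitted_state(small_dataset, bundled_table) -> aa.EncoderState:
    return aa.fit_encoder(small_dataset, table=bundled_table)


@pytest.fixture(scope="session")
def encoded_vectors(small_dataset, fitted_state):
    return aa.encode_dataset(small_dataset, fitted_state)


@pytest.fixture(scope="session")
def toy_clusters():
    """Two well-separated Gaussian clusters in the 400-dim feature space.

    40 samples, labels balanced; linearly separable by construction.
    """
    rng = np.random.default_rng(7)
    centers = np.zeros((2, 400))
    centers[0, :200] = 1.0
    centers[1, 200:] = 1.0
    X = np.vstack(
        [rng.normal(centers[c], 0.1, size=(20, 400)) for c in (0, 1)]
    )
    y = np.repeat([0, 1], 20)
    return X, y
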