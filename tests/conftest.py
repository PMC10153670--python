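import numpy as np
import pytest

import stnet as st


@pytest.fixture(scope="session")
def blobs3():
    """Moderately separated 3-class Gaussian blobs, min-max normalized."""
    ds = st.make_synthetic("blobs", n_per_class=50, n_features=4,
                           n_classes=3, noise=1.0, seed=1)
    return st.minmax_normalize(ds)


@pytest.fixture()
def single_synapse_layer():
    """One presynaptic neuron, one synapse: v=2, d=1, tau=7."""
    return st.SRMLayer(weights=np.array([[[2.0]]]), delays=np.array([1.0]))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
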