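import numpy as np
import pytest

import follownet as fn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ensemble():
    """A modest 2-D ensemble (radius 5, default tuning) shared across tests."""
    return fn.sample_tuning(400, 2, 5.0, "intercept_maxrate",
                            np.random.default_rng(7))


@pytest.fixture(scope="session")
def tiny_linear_net():
    """A 60+60-neuron network on the linear oscillator, with solved decoders."""
    from follownet.experiments import build_network

    net, (rng_in, rng_noise) = build_network("linear", n_neurons=60, seed=11)
    return net, rng_in
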