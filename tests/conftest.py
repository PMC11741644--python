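import numpy as np
import pytest

from neoseg import (
    ConvLayerAction,
    PhantomSpec,
    assemble_configuration,
    encode_conv_action,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom_dataset():
    """Eight small 2D phantoms reused across network and search tests."""
    spec = PhantomSpec(shape=(16, 16), seed=5)
    return generate_dataset(8, spec, seed=5)


@pytest.fixture
def minimal_config():
    """The smallest genotype: nineteen <32,1,1> convolutions, max pooling."""
    return assemble_configuration([0] * 19, [0, 0])


@pytest.fixture
def small_config():
    """A light genotype with 3x3 in-plane kernels for trainability tests."""
    idx = encode_conv_action(ConvLayerAction(32, 3, 3))
    return assemble_configuration([idx] * 19, [0, 1])
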