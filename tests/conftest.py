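import numpy as np
import pytest

from smfnet.model import nano_config
from smfnet.synthetic import generate_samples, tiny_spec
from smfnet.text import Vocabulary


@pytest.fixture(scope="session")
def phantoms():
    """Four deterministic 32x32 phantom samples."""
    return generate_samples(4, tiny_spec(), seed=7)


@pytest.fixture(scope="session")
def vocab(phantoms):
    return Vocabulary.build([s.text for s in phantoms]
                            + ["no finding", "no lesion in the organ"])


@pytest.fixture(scope="session")
def nano_model(vocab):
    """A small untrained network shared by read-only tests."""
    from smfnet.model import SMFNet
    return SMFNet(nano_config(), vocab, np.random.default_rng(0))
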