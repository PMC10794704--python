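import numpy as np
import pytest

from neuronet19.phantoms import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_batch():
    """40 phantoms (10 per class) with ground truth, reused across tests."""
    spec = PhantomSpec()
    out = []
    for i in range(10):
        for c in range(4):
            out.append(generate_phantom(c, spec, seed=100 + i))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
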