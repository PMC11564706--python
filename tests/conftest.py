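import numpy as np
import pytest

from breastmorph.labelmap import TissueSchema
from breastmorph.phantom import generate_phantom, phantom_suite


@pytest.fixture(scope="session")
def preset_case():
    """Factory fixture caching generated phantom presets per session."""
    cache = {}

    def get(name):
        if name not in cache:
            cache[name] = generate_phantom(phantom_suite(name))
        return cache[name]

    return get


@pytest.fixture(scope="session")
def schema():
    return TissueSchema.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
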