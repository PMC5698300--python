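import numpy as np
import pytest

from lbdkit.catalog import load_reference_catalog


@pytest.fixture(scope="session")
def reference_catalog():
    """The bundled 50-gene grapevine locus table."""
    return load_reference_catalog()


@pytest.fixture(scope="session")
def by_name(reference_catalog):
    return {l.short_name: l for l in reference_catalog}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
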