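import numpy as np
import pytest

from nucsite import fixtures, structio, templates

TOY_LIGANDS = ["AMP", "ADP", "ATP", "ANP", "GDP", "GTP", "GNP",
               "FMN", "FAD", "NAD", "NAP"]


@pytest.fixture(scope="session")
def defs():
    return structio.load_fragment_definitions()


@pytest.fixture(scope="session")
def toy_complex(defs):
    """Factory with a session cache: toy_complex('ATP', seed=1)."""
    cache = {}

    def build(component_id, seed=1):
        key = (component_id, seed)
        if key not in cache:
            cache[key] = fixtures.make_toy_complex(component_id, defs,
                                                   seed=seed)
        return cache[key]

    return build


@pytest.fixture(scope="session")
def amp_complex(toy_complex):
    return toy_complex("AMP", seed=1)


@pytest.fixture(scope="session")
def amp_library(amp_complex, defs):
    return templates.Library(templates.extract_binding_sites(amp_complex, defs))


@pytest.fixture()
def rng():
    return np.random.default_rng(20120327)
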