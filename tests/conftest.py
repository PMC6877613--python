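import logging

import numpy as np
import pytest

logging.getLogger("chemoflow").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    # fresh, identically seeded generator per test: results never depend on
    # test execution order
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pathway_defaults():
    from chemoflow.chemo_pathway import PathwayParams
    return PathwayParams()
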