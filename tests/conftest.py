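import numpy as np
import pytest
from hypothesis import settings

import cellscaling as cs

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")

# measured parameters for two reference lines of the panel
LINE_4434 = (3.49e-6, 0.16)
LINE_24038 = (6.38e-7, 0.49)


@pytest.fixture(scope="session")
def params_4434() -> cs.GrowthDivisionParams:
    return cs.GrowthDivisionParams(alpha=LINE_4434[0], beta=LINE_4434[1])


@pytest.fixture(scope="session")
def sim_4434(params_4434):
    """One full agent simulation (1,000 -> 20,000 cells) at the
    reference parameters; shared across tests for speed."""
    return cs.run_agent_simulation(params_4434, cs.SimConfig(rng_seed=3))


@pytest.fixture(scope="session")
def panel():
    """Default synthetic 11-line panel."""
    return cs.make_panel(cs.PanelSpec(rng_seed=11))


@pytest.fixture(scope="session")
def omics(panel):
    """Default synthetic omics matrices with planted scaling features."""
    return cs.make_omics(cs.OmicsSpec(rng_seed=11), panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
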