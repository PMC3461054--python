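import numpy as np
import pytest

from coilmelt import simulate as sim


@pytest.fixture(scope="session")
def noiseless_melt():
    """Noiseless two-state melt from the default generator parameters."""
    return sim.gen_melt_curve(sim.MeltGenerator())


@pytest.fixture(scope="session")
def default_generator():
    return sim.MeltGenerator()


@pytest.fixture(scope="session")
def ideal_helix30():
    return sim.gen_ideal_helix(30)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
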