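import pytest

from nanobridge import mechanics as mech
from nanobridge import synthetic as syn
from nanobridge import transfer as tr


@pytest.fixture(scope="session")
def constants():
    return mech.DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def actin():
    return mech.ACTIN


@pytest.fixture(scope="session")
def tubulin():
    return mech.TUBULIN


@pytest.fixture(scope="session")
def facs_scenario():
    """One co-culture gating scenario shared across transfer tests."""
    gate = tr.GateSpec()
    unstained = syn.gen_facs_events("control", n_events=20_000, seed=101, unstained=True)
    co = syn.gen_facs_events("co_culture", n_events=50_000, seed=102)
    control = syn.gen_facs_events("control", n_events=50_000, seed=103)
    return {"gate": gate, "unstained": unstained, "co": co, "control": control}
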