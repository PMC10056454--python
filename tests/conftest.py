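import pytest

from emol.compounds import default_registry
from emol.ledger import BatchObservation
from emol.stoich import default_network


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def network():
    return default_network()


@pytest.fixture()
def eq1_batch():
    """A vial that performs exactly one mmol-extent of the 5:3
    ethanol/acetate chain elongation: 5 mmol ethanol + 3 mmol acetate
    fully converted to 4 mmol butyrate + 2 mmol H2 (water unmeasured)."""
    return BatchObservation(
        vial="A",
        transfer=0,
        liquid_volume_l=0.1,
        liquid_initial_mm={"ethanol": 50.0, "acetic acid": 30.0},
        liquid_final_mm={"ethanol": 0.0, "acetic acid": 0.0, "butyric acid": 40.0},
        gas_initial_mmol={"H2": 0.0},
        gas_final_mmol={"H2": 2.0},
    )
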