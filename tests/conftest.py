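import pytest

from gh99kit import load_reference
from gh99kit.synth import (
    ContaminantSpec,
    PlantedState,
    SimulationConfig,
    SubfamilySpec,
    simulate_family,
)


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def small_cohort():
    """Three subfamilies with distinct planted motif states, plus truth."""
    config = SimulationConfig(
        subfamilies=[
            SubfamilySpec("MANEA", n=8, p=0.1, planted=PlantedState("Y", "N", "EWHE")),
            SubfamilySpec("MANEAL", n=8, p=0.1, planted=PlantedState("Y", "N", "EWHE")),
            SubfamilySpec("CMANEAL", n=8, p=0.1, planted=PlantedState("Y", "H", "QWHE")),
        ],
        seed=11,
    )
    return simulate_family(config)


@pytest.fixture(scope="session")
def contaminated_cohort():
    """Eleven in-group records plus one planted cross-taxogroup contaminant."""
    config = SimulationConfig(
        subfamilies=[SubfamilySpec("GroupA", n=11, p=0.05)],
        contaminants=[ContaminantSpec(1, "GroupA", "GroupB")],
        seed=7,
    )
    return simulate_family(config)
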