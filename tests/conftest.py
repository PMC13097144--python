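import numpy as np
import pytest

from foxscreen import gating, synth


@pytest.fixture(scope="session")
def small_layout():
    return synth.design_layout(plate_id="T1", n_compounds=24)


@pytest.fixture(scope="session")
def neutral_effects(small_layout):
    return {
        e.compound_id: synth.CompoundEffect(compound_id=e.compound_id)
        for e in small_layout.wells.values()
        if e.role == "compound"
    }


@pytest.fixture(scope="session")
def neutral_plate(small_layout, neutral_effects):
    """Simulated 40-well plate (24 compounds + 16 controls), 2000 events/well."""
    return synth.simulate_plate(small_layout, neutral_effects, n_events=2000, seed=7)


@pytest.fixture(scope="session")
def plate_summaries(neutral_plate, small_layout):
    tables, _ = neutral_plate
    return gating.summarize_plate(tables, small_layout)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
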