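import numpy as np
import pandas as pd
import pytest

from aquibiome import bioenergetics as be
from aquibiome import geochem as gc
from aquibiome.otu import OtuTable


@pytest.fixture(scope="session")
def wells() -> list[gc.WellChemistry]:
    return gc.load_reference_wells()

@pytest.fixture(scope="session")
def published_classes() -> dict[str, gc.SulfateClass]:
    return gc.load_reference_classes()

@pytest.fixture(scope="session")
def energy_config() -> be.EnergyConfig:
    return be.EnergyConfig()

@pytest.fixture()
def toy_table() -> OtuTable:
    """Four samples, two per group, with a strong group contrast."""
    counts = pd.DataFrame(
        {
            "OTU_1": [30, 28, 2, 1],
            "OTU_2": [5, 6, 4, 5],
            "OTU_3": [1, 2, 30, 29],
        },
        index=["a1", "a2", "b1", "b2"],
    )
    meta = pd.DataFrame(
        {
            "well_id": ["w1", "w2", "w3", "w4"],
            "fraction": ["ATT", "ATT", "SUS", "SUS"],
            "sulfate_class": ["HS", "HS", "NS", "NS"],
        },
        index=counts.index,
    )
    return OtuTable(counts, sample_meta=meta)

@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20130624)
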