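import numpy as np
import pytest

import enamelseason as es
from enamelseason.synthetic_data import (
    BodyWaterParams,
    CohortScenario,
    synth_body_water,
    synth_tooth,
    synth_water_year,
)


@pytest.fixture
def geometry():
    return es.ToothGeometry()


@pytest.fixture
def water():
    return synth_water_year()


@pytest.fixture
def make_tooth(geometry, water):
    """Factory for seeded synthetic teeth under the default study conditions."""

    def _make(seed, meteoric_only=False, **scenario_kwargs):
        rng = np.random.default_rng(seed)
        if meteoric_only:
            monthly = es.water_to_phosphate(water.values)
        else:
            monthly = synth_body_water(water, BodyWaterParams(), rng)
        scenario = CohortScenario(**scenario_kwargs)
        return synth_tooth(
            monthly, geometry, scenario, rng, specimen_id=f"synthetic-{seed}"
        )

    return _make
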