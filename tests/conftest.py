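import dataclasses

import numpy as np
import pytest

from gcamp_plasticity import build_control_reference, make_cohort
from gcamp_plasticity.pipeline import control_changes, quantify_cohort
from gcamp_plasticity.synthetic_cohort import VEHICLE_DESIGN


@pytest.fixture(scope="session")
def vehicle_cohort():
    """A vehicle-injected control cohort shared across tests."""
    return make_cohort(dataclasses.replace(VEHICLE_DESIGN, seed=11))


@pytest.fixture(scope="session")
def vehicle_table(vehicle_cohort):
    return quantify_cohort(vehicle_cohort)


@pytest.fixture(scope="session")
def control_ref(vehicle_table):
    """Control reference band built from the vehicle arm."""
    return build_control_reference(control_changes(vehicle_table))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
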