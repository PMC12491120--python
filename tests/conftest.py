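import numpy as np
import pytest

from psmadyn.core import FrameSchedule
from psmadyn.simulate import (
    KineticGroundTruth,
    make_input_function,
    reference_fine_curve,
    simulate_lesion_tac_srtm,
    simulate_reference_tac,
)


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.dynamic_55frame()


@pytest.fixture(scope="session")
def truth():
    return KineticGroundTruth()  # R1=1.2, k2=0.3/min, BP_ND=2.0


@pytest.fixture(scope="session")
def input_fn(truth):
    return make_input_function(truth.input_function_params)


@pytest.fixture(scope="session")
def reference_fine(input_fn, truth, schedule):
    return reference_fine_curve(input_fn, truth.reference_params, schedule)


@pytest.fixture(scope="session")
def reference_tac(input_fn, truth, schedule):
    return simulate_reference_tac(input_fn, truth.reference_params, schedule)


@pytest.fixture(scope="session")
def lesion_tac(reference_fine, truth, schedule):
    return simulate_lesion_tac_srtm(reference_fine, truth, schedule)


@pytest.fixture(scope="session")
def short_schedule():
    """A 20-frame, 20-min schedule for cheap fitting tests."""
    durations = np.concatenate([np.full(10, 30.0), np.full(10, 90.0)])
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations)
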