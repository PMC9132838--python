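import numpy as np
import pytest

from mbfagree.kinetics import FrameSchedule, TimeActivityCurve, default_schedule
from mbfagree.synthdata import InputFunctionSpec, simulate_input_function


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def blood_tac(schedule):
    """Deterministic synthetic blood-pool input curve."""
    return simulate_input_function(InputFunctionSpec(), schedule)


@pytest.fixture(scope="session")
def step_input_schedule():
    """Schedule with a negligible first frame so a constant TAC is flat
    from t=0 (the piecewise-linear knots otherwise ramp up to the first
    frame mid-time)."""
    durs = np.concatenate([[1e-6], np.full(72, 5.0)])
    starts = np.concatenate([[0.0], 1e-6 + np.arange(72) * 5.0])
    return FrameSchedule(starts, durs)


@pytest.fixture(scope="session")
def constant_input(step_input_schedule):
    """Ca == 1 for t >= 0 (to numerical precision)."""
    return TimeActivityCurve(step_input_schedule,
                             np.ones(step_input_schedule.n_frames),
                             region_id="LV_cavity", is_blood_pool=True)
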