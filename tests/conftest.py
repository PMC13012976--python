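import numpy as np
import pytest

from neurolap import WorkloadStudy, generate_track, seven_turn_plan


def circle_xy(radius: float, spacing: float = 5.0) -> np.ndarray:
    n = int(round(2 * np.pi * radius / spacing))
    ang = 2 * np.pi * np.arange(n) / n
    return radius * np.column_stack([np.cos(ang), np.sin(ang)])


@pytest.fixture(scope="session")
def seven_track():
    return generate_track(seven_turn_plan())


@pytest.fixture(scope="session")
def fitted_study():
    """The reference 15-driver calibrated cohort, simulated and fitted."""
    study, cohort = WorkloadStudy.simulate(seed=7)
    return study, cohort, study.fit()
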