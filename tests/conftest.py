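import numpy as np
import pytest

from pbifkit import (
    POPULATION_PBIF_PARAMS,
    FengParams,
    SampledCurve,
    default_schedule,
    feng_eval,
)


@pytest.fixture(scope="session")
def schedule62():
    return default_schedule()


@pytest.fixture(scope="session")
def printed_params():
    """The published population input-function parameter set (normalized units)."""
    return POPULATION_PBIF_PARAMS


@pytest.fixture(scope="session")
def printed_curve(schedule62, printed_params):
    """Noiseless curve from the population parameters on the 62-frame schedule."""
    values = feng_eval(printed_params, schedule62.mid_min)
    return SampledCurve(schedule62.start_min, schedule62.end_min, values, "population")


def feng_curve(params: FengParams, schedule) -> SampledCurve:
    """Sample a Feng model on a frame schedule (noiseless)."""
    values = feng_eval(params, schedule.mid_min)
    return SampledCurve(schedule.start_min, schedule.end_min, values, "feng")
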