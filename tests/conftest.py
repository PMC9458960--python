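"""Shared fixtures: the standard 63 kg model and cached baseline trials.

Trials are expensive (seconds each), so the overground and ideal-belt
baselines at the natural walking speed are computed once per session and
shared by the experiment- and acceptance-level tests.
"""

import numpy as np
import pytest

from treadgait import (
    TreadmillSpec,
    TrialConfig,
    build_model,
    generate_reference,
    run_trial,
)

STANDARD_MASS = 63.0
STANDARD_HEIGHT = 1.73
NATURAL_SPEED = 1.05
TRIAL_DURATION = 12.0


@pytest.fixture(scope="session")
def model63():
    return build_model(STANDARD_MASS, STANDARD_HEIGHT)


@pytest.fixture(scope="session")
def ref105(model63):
    return generate_reference(NATURAL_SPEED, model63, seed=1)


@pytest.fixture(scope="session")
def overground_trial():
    return run_trial(TrialConfig(speed=NATURAL_SPEED, duration=TRIAL_DURATION))


@pytest.fixture(scope="session")
def ideal_treadmill_trial():
    return run_trial(TrialConfig(
        speed=NATURAL_SPEED, duration=TRIAL_DURATION,
        treadmill=TreadmillSpec(target_speed=NATURAL_SPEED, ideal=True),
    ))
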