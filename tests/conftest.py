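import numpy as np
import pytest

from persifade import (
    DisplayGeometry,
    calibrate_offset,
    default_profiles,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def geom():
    return DisplayGeometry()


@pytest.fixture(scope="session")
def calibrated_600ms():
    """Decay calibrated to fall through 0.01 at 600 ms with a = 50/s."""
    return calibrate_offset(50.0, 0.6, 0.01, 1.2)


@pytest.fixture(scope="session")
def calibrated_family():
    """The six calibrated decays for offset targets 200..1200 ms."""
    return {t: calibrate_offset(50.0, t / 1000.0, 0.01, 1.2)
            for t in (200, 400, 600, 800, 1000, 1200)}


@pytest.fixture(scope="session")
def exp1_trials():
    """One simulated run of the annulus experiment (9 subjects, 320 trials)."""
    return simulate_experiment(1, default_profiles(1, 9, seed=3), seed=3)


@pytest.fixture(scope="session")
def exp2_trials():
    """One simulated run of the contrast-decay proxy experiment (4 subjects)."""
    return simulate_experiment(2, default_profiles(2, seed=5), seed=5)
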