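import numpy as np
import pytest

from svsbalance import CohortSpec, MarkerTrial, ThresholdProfile
from svsbalance.kinematics import MARKER_NAMES


@pytest.fixture(scope="session")
def spec():
    return CohortSpec()


@pytest.fixture(scope="session")
def profile():
    return ThresholdProfile(1, 600, 300)


def make_trial(
    task="standing",
    rate=120.0,
    duration=5.0,
    chest_x=None,
    chest_z=None,
    overrides=None,
    balance="unchallenged",
):
    """Minimal hand-built trial: static markers unless overridden.

    ``chest_x``/``chest_z`` replace the chest AP/ML coordinate; ``overrides``
    maps marker name -> (n, 3) array.
    """
    n = int(round(rate * duration)) + 1
    markers = {}
    defaults = {
        "head": (0.0, 1.70, 0.0),
        "chest": (0.0, 1.40, 0.0),
        "heel_L": (-0.05, 0.02, -0.06),
        "heel_R": (-0.05, 0.02, 0.06),
        "midfoot_L": (0.08, 0.03, -0.06),
        "midfoot_R": (0.08, 0.03, 0.06),
        "fifthmet_L": (0.10, 0.03, -0.085),
        "fifthmet_R": (0.10, 0.03, 0.085),
        "toe_L": (0.16, 0.02, -0.06),
        "toe_R": (0.16, 0.02, 0.06),
    }
    for name in MARKER_NAMES:
        markers[name] = np.tile(np.array(defaults[name]), (n, 1))
    if chest_x is not None:
        markers["chest"] = markers["chest"].copy()
        markers["chest"][:, 0] = chest_x
    if chest_z is not None:
        markers["chest"] = markers["chest"].copy()
        markers["chest"][:, 2] = chest_z
    if overrides:
        for name, arr in overrides.items():
            markers[name] = np.asarray(arr, dtype=float)
    return MarkerTrial(
        participant_id=1,
        task=task,
        balance=balance,
        stimulation="sham",
        technique="sinusoidal",
        trial_index=1,
        rate=rate,
        markers=markers,
    )


@pytest.fixture
def static_standing_trial():
    return make_trial()
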