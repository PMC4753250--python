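import numpy as np
import pytest
from hypothesis import settings

from larvarc import AcquisitionConfig, BehaviorState, BehaviorTrack, StimulusTrace

# seeded, repeatable hypothesis runs
settings.register_profile("larvarc", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("larvarc")

RUN = int(BehaviorState.RUN)
TURN = int(BehaviorState.TURN)


def make_track(states: str, animal_id: str = "a0", valid: str | None = None) -> BehaviorTrack:
    """Build a track from a compact string, e.g. 'RRRTTR' ('?' = invalid)."""
    codes = np.array([TURN if c == "T" else RUN for c in states], dtype=np.uint8)
    if valid is None:
        v = np.array([c != "?" for c in states])
    else:
        v = np.array([c == "1" for c in valid])
    return BehaviorTrack(animal_id=animal_id, state=codes, valid=v)


@pytest.fixture
def config() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture
def constant_on_stimulus() -> StimulusTrace:
    return StimulusTrace(led_state=np.ones(400, dtype=np.uint8), frame_rate_hz=4.0)
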