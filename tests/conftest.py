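import numpy as np
import pytest

from depthfall.config import DetectorParams, SUBJECTS
from depthfall.io import DepthFrame
from depthfall.segmentation import PersonBlob
from depthfall.simulate import SceneSpec
from depthfall.state_machine import DetectorState, Observation, step


@pytest.fixture(scope="session")
def params():
    return DetectorParams()


@pytest.fixture(scope="session")
def subject():
    return SUBJECTS[0]  # 177 cm male


@pytest.fixture(scope="session")
def quiet_scene():
    """Noise- and dropout-free scene for exact geometric assertions."""
    return SceneSpec(noise_sigma_mm=0.0, border_dropout_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_scene():
    return SceneSpec(seed=11)


def scalar_observation(t, act, params):
    """Build a minimal observation carrying a prescribed head distance."""
    if act is None:
        return Observation(timestamp_s=t, frame=None, person=None, blobs=[])
    grid = np.full((8, 8), max(int(round(act)), 1), dtype=np.uint16)
    frame = DepthFrame(grid=grid, timestamp_s=t)
    mask = np.ones((8, 8), dtype=bool)
    blob = PersonBlob(mask=mask, area_px=64, act_dist_mm=float(act),
                      bounding_box=(0, 0, 8, 8))
    return Observation(timestamp_s=t, frame=frame, person=blob, blobs=[blob])


def run_scalar_series(series, params, classifier=None):
    """Drive the state machine with a scalar head-distance series.

    ``series`` entries are head distances in mm or None (person absent).
    Returns the final detector state.
    """
    state = DetectorState(params=params)
    for i, act in enumerate(series):
        obs = scalar_observation(i / params.fps, act, params)
        state = step(state, obs, params, frame_classifier=classifier)
    return state
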