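import numpy as np
import pytest

from chasescan.events_basic import segment_basic
from chasescan.preproc import preprocess
from chasescan.stimulus import StimulusParams, generate_trial
from chasescan.synthgaze import ObserverParams, simulate_observer


@pytest.fixture(scope="session")
def dc_trial():
    return generate_trial(StimulusParams(), "DC", 3)


@pytest.fixture(scope="session")
def nc_trial():
    return generate_trial(StimulusParams(), "NC", 5)


@pytest.fixture(scope="session")
def gaze_group_clean(dc_trial):
    return simulate_observer(
        dc_trial, ObserverParams(strategy="group", noise_sd=0.0, blink_rate=0.0), 11)


@pytest.fixture(scope="session")
def gaze_single_clean(dc_trial):
    return simulate_observer(
        dc_trial, ObserverParams(strategy="single_agent", noise_sd=0.0,
                                 blink_rate=0.0), 11)


@pytest.fixture(scope="session")
def gaze_group_noisy(dc_trial):
    return simulate_observer(
        dc_trial, ObserverParams(strategy="group", noise_sd=0.1), 11)


@pytest.fixture(scope="session")
def fused_group_clean(dc_trial, gaze_group_clean):
    g = gaze_group_clean
    return preprocess(g.time, g.left_xy, g.right_xy, dc_trial.n_frames)


@pytest.fixture(scope="session")
def events_group_clean(dc_trial, fused_group_clean):
    return segment_basic(fused_group_clean, dc_trial)


def rasterize_kinds(events, n_frames):
    out = np.full(n_frames, "none", dtype=object)
    for e in events:
        out[e.start:e.end] = e.kind
    return out
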