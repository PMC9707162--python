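import numpy as np
import pytest

from noreport import eyeproc
from noreport import paradigm as pg
from noreport.synth import EyeDynamicsParams, generate_eye_session


def make_schedule(n_events, start=10.0, spacing=16.0):
    """Evenly spaced threshold-condition stimulus events."""
    return [
        pg.StimulusEvent(
            onset=start + spacing * i,
            location_set="quadrant",
            location=1 + i % 4,
            opacity_condition="threshold",
            opacity=0.1,
        )
        for i in range(n_events)
    ]


def processed_epochs(rec, anchors):
    """Standard chain: blink detect -> interpolate -> msacc detect -> epoch."""
    blinks, _ = eyeproc.detect_blinks(rec)
    interp = eyeproc.interpolate_artifacts(rec, blinks)
    msaccs = eyeproc.detect_microsaccades(
        interp, exclude_mask=interp.info["artifact_valid"]
    )
    return eyeproc.epoch_eye(
        interp,
        anchors,
        blink_times=[b[0] for b in blinks],
        msacc_times=[m.onset for m in msaccs],
    )


@pytest.fixture(scope="session")
def default_eye_params():
    return EyeDynamicsParams()


@pytest.fixture(scope="session")
def labeled_eye_session():
    """A 150-trial eye session with known perceived labels, processed into
    epochs; shared by the feature/classifier tests."""
    rng = np.random.default_rng(2024)
    schedule = make_schedule(150)
    labels = rng.random(150) < 0.5
    rec = generate_eye_session(schedule, labels, seed=77)
    epochs = processed_epochs(rec, [e.onset for e in schedule])
    assert len(epochs) == len(schedule)
    return schedule, labels, rec, epochs
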