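import numpy as np
import pytest

from catrans import (
    EventTrain,
    FluorescenceTrace,
    OccupancyTrack,
    SALINE,
    COCAINE,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trace(values, start_time=0.0, sampling_rate=10.0, neuron_id="n0"):
    return FluorescenceTrace(
        neuron_id=neuron_id, start_time=start_time,
        sampling_rate=sampling_rate, values=np.asarray(values, dtype=float),
    )


def make_train(times, span, neuron_id="n0"):
    return EventTrain(neuron_id=neuron_id, event_times=np.asarray(times, dtype=float), span=span)


def make_track(dwells, sampling_rate=10.0):
    """Build an occupancy track from [(chamber, duration_s), ...] at 10 Hz."""
    labels, bounds = [], [0.0]
    for chamber, dur in dwells:
        bounds.append(bounds[-1] + dur)
        labels.append(chamber)
    end = bounds[-1]
    times = np.arange(0.0, end, 1.0 / sampling_rate)
    starts = np.asarray(bounds[:-1])
    idx = np.searchsorted(starts, times, side="right") - 1
    chambers = np.asarray(labels, dtype=object)[idx]
    return OccupancyTrack(times=times, chambers=chambers, session_end=end)


@pytest.fixture
def alternating_track():
    """100 s of strict 10 s / 10 s alternation between the two chambers."""
    return make_track([(SALINE, 10.0), (COCAINE, 10.0)] * 5)
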