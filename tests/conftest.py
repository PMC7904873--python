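import numpy as np
import pytest

from neurogut import (
    ContinuousRecording,
    EventSeries,
    StateHypnogram,
    gen_hypnogram,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def wake_sws_hypnogram() -> StateHypnogram:
    return gen_hypnogram([("WAKE", 600.0), ("SWS", 600.0)])


@pytest.fixture
def sine_recording() -> ContinuousRecording:
    """20 s of a pure 10 Hz unit-amplitude sinusoid at 1 kHz."""
    rate = 1000.0
    t = np.arange(0, 20, 1 / rate)
    return ContinuousRecording(np.sin(2 * np.pi * 10 * t), rate)


def make_events(onsets, artifacts=None) -> EventSeries:
    return EventSeries(np.asarray(onsets, dtype=float), artifacts)
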