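import numpy as np
import pytest

from aquapos.geo import LocalPoint
from aquapos.simulator import (
    ClockErrorModel,
    DetectionRangeModel,
    Receiver,
    TransmitterSpec,
    equilateral_array,
    simulate_detections,
    simulate_emissions,
)


class ConstantRangeModel:
    """Range model stub with a fixed detection probability."""

    def __init__(self, p: float):
        self.p = p

    def probability(self, distance):
        return np.full_like(np.asarray(distance, dtype=float), self.p)


@pytest.fixture
def triangle():
    """Three receivers on a 270 m equilateral triangle, origin-centred."""
    return equilateral_array(spacing=270.0, n=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_clock():
    return ClockErrorModel(jitter_sd=0.0)


def make_noiseless_detections(receivers, source, emission_times, c=1500.0,
                              tag_id="tag"):
    """Exact-arrival detections of a stationary source at every receiver."""
    positions = np.tile(np.asarray(source, dtype=float), (len(emission_times), 1))
    return simulate_detections(
        np.asarray(emission_times, dtype=float),
        positions,
        receivers,
        ConstantRangeModel(1.0),
        ClockErrorModel(jitter_sd=0.0),
        c,
        np.random.default_rng(0),
        tag_id=tag_id,
    )


@pytest.fixture
def pinger():
    return TransmitterSpec(tag_id="p1", mode="continuous", period=3.0, depth=15.0)
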