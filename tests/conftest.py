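import numpy as np
import pytest

from muflex.spiketrain import PopulationRecording, SpikeTrain


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def regular_train(rate_hz: float, duration: float, unit_id: str = "u0",
                  start: float = 0.05) -> SpikeTrain:
    times = np.arange(start, duration, 1.0 / rate_hz)
    return SpikeTrain(unit_id, times[times < duration])


@pytest.fixture()
def regular_pop():
    """Three regular units at 8/10/12 pps over 10 s, fs 2048."""
    trains = tuple(
        regular_train(r, 10.0, f"u{i}") for i, r in enumerate((8.0, 10.0, 12.0))
    )
    return PopulationRecording(trains, duration=10.0, fs=2048.0)
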