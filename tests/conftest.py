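import numpy as np
import pytest

import eegspatcorr as esc


@pytest.fixture(scope="session")
def montage():
    return esc.standard_montage()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording():
    """A 30 s two-channel sinusoid recording with alternating conditions."""
    fs = 500.0
    t = np.arange(int(30 * fs)) / fs
    data = np.stack([np.sin(2 * np.pi * 5 * t), np.sin(2 * np.pi * 10 * t)])
    intervals = [
        esc.ConditionInterval(0, 15, "eyes_closed"),
        esc.ConditionInterval(15, 30, "eyes_open"),
    ]
    return esc.Recording(data, fs, ["FC1", "FT7"], intervals)


def two_channel_config(**kwargs):
    """Small simulation config used across tests."""
    defaults = dict(
        channel_labels=("FC1", "FT7"),
        duration=300.0,
        carrier_bands=(("theta", 3.0, 7.0),),
        condition_schedule=esc.alternating_schedule(10, 30.0),
        seed=0,
    )
    defaults.update(kwargs)
    return esc.SimulationConfig(**defaults)
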