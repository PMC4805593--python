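import numpy as np
import pytest

from bgcompete import ChannelParams, ChannelInput, DecisionParams, StateTrajectory


@pytest.fixture
def quiet_params() -> ChannelParams:
    """Deterministic (zero-noise) channel with the default constants."""
    return ChannelParams(noise_sd=0.0)


@pytest.fixture
def symmetric_input() -> ChannelInput:
    return ChannelInput(I_d=0.5, I_i=0.5)


@pytest.fixture
def dp() -> DecisionParams:
    return DecisionParams()


def make_ramp_trajectory(slope: float, horizon: float = 1000.0,
                         dt: float = 1.0, base: float = 2.0) -> StateTrajectory:
    """Synthetic trajectory whose d - i difference is exactly slope * t."""
    times = np.arange(0.0, horizon + dt / 2, dt)
    half = slope * times / 2.0
    return StateTrajectory(times=times, d_rate=base + half, i_rate=base - half)
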