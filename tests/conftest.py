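import numpy as np
import pytest

from stressloop.characteristics import make_catalog
from stressloop.signal_model import Channel, ChannelSet, SignalLog
from stressloop.subject_sim import default_characteristics, make_subject


@pytest.fixture
def channels():
    """Four equal-rate channels, all +1 direction, for hand-checkable algebra."""
    return ChannelSet([
        Channel("hr", form="cardiac", sampling_rate=10.0),
        Channel("hrv", form="cardiac", sampling_rate=10.0),
        Channel("bp", form="hemodynamic", sampling_rate=10.0),
        Channel("eda", form="sympathetic", sampling_rate=10.0),
    ])


@pytest.fixture
def catalog():
    return make_catalog(25, seed=11)


@pytest.fixture
def easy_subject():
    return make_subject("easy", seed=42)


@pytest.fixture
def specs():
    return default_characteristics(seed=42)


def constant_log(channels, value, t0=0.0, t1=20.0):
    """Constant-valued stream on every channel over [t0, t1]."""
    series = {}
    for ch in channels:
        t = t0 + (np.arange(int((t1 - t0) * ch.sampling_rate)) + 1) / ch.sampling_rate
        series[ch.name] = (t, np.full_like(t, float(value)))
    return SignalLog(series)


def step_log(channels, t_step, base, height, noise_sd=0.0, seed=0, t0=0.0, t1=40.0):
    """Stream with an instantaneous step of ``height`` at ``t_step`` on every channel."""
    rng = np.random.default_rng(seed)
    series = {}
    for ch in channels:
        t = t0 + (np.arange(int((t1 - t0) * ch.sampling_rate)) + 1) / ch.sampling_rate
        v = np.full_like(t, float(base)) + np.where(t >= t_step, float(height), 0.0)
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, size=t.size)
        series[ch.name] = (t, v)
    return SignalLog(series)
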