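import numpy as np
import pytest

import mechpath as mp


@pytest.fixture(scope="session")
def csp_network():
    """The default six-element network (five strands + loop, 19 nm at 40 pN)."""
    return mp.default_network()


@pytest.fixture(scope="session")
def single_element_network():
    """One-barrier network with the experimental global rate scale."""
    return mp.default_network(n_elements=1)


@pytest.fixture
def staircase_trace():
    """Noiseless two-step clamp staircase 0 -> 3 -> 19 nm at 40 pN, 1 kHz."""
    fs = 1000.0
    t = np.arange(0, 3.0, 1.0 / fs)
    ext = np.where(t < 1.0, 0.0, np.where(t < 2.0, 3.0, 19.0))
    return mp.Trace(
        time=t,
        extension=ext,
        force=np.full(t.size, 40.0),
        protocol="clamp",
        sampling_rate=fs,
        trace_id="staircase",
        setpoint=40.0,
    )


@pytest.fixture(scope="session")
def make_clamp():
    """Factory for piecewise-constant clamp traces (levels nm, dwells s)."""
    return make_clamp_trace


def make_clamp_trace(levels, dwells, fs=1000.0, force=40.0, noise_sd=0.0, seed=0):
    """Piecewise-constant clamp trace from (level nm, dwell s) pairs."""
    rng = np.random.default_rng(seed)
    parts = []
    for level, dwell in zip(levels, dwells):
        n = int(round(dwell * fs))
        parts.append(np.full(n, float(level)))
    ext = np.concatenate(parts)
    if noise_sd:
        ext = ext + rng.normal(0, noise_sd, ext.size)
    t = np.arange(ext.size) / fs
    return mp.Trace(
        time=t,
        extension=ext,
        force=np.full(ext.size, force),
        protocol="clamp",
        sampling_rate=fs,
        trace_id="synthetic",
        setpoint=force,
    )
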