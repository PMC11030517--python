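import numpy as np
import pandas as pd
import pytest

from frustranet.metrics import TraceSet


@pytest.fixture
def antiphase_square_waves() -> TraceSet:
    """Two anti-phase 50%-duty square waves with values {0, 1}, period 20."""
    T = 20.0
    dt = 0.5
    t = np.arange(0, 8 * T, dt)
    a = ((t % T) < T / 2).astype(float)
    return TraceSet(
        times=t, values=pd.DataFrame({"a": a, "b": 1.0 - a}), period=T
    )


@pytest.fixture
def identical_traces() -> TraceSet:
    t = np.arange(0, 160.0, 0.5)
    y = 1.0 + np.sin(2 * np.pi * t / 20.0) ** 2
    return TraceSet(
        times=t, values=pd.DataFrame({"a": y, "b": y.copy(), "c": y.copy()}),
        period=20.0,
    )
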