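import numpy as np
import pytest

from attnaf.core import RRWindow
from attnaf.synth import SynthConfig, synth_windows


@pytest.fixture(scope="session")
def default_windows():
    """Moderate default-preset dataset shared by read-only tests."""
    return synth_windows(SynthConfig(n_windows=200, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_window(values, label=0, record_id="r0", window_index=0):
    return RRWindow(values=np.asarray(values, dtype=float), label=label,
                    record_id=record_id, window_index=window_index)


@pytest.fixture()
def uniform_windows():
    """10 windows, 5 per class, constant values: minimal balanced dataset."""
    out = []
    for k in range(5):
        out.append(make_window([0.8] * 30, label=0, record_id=f"a{k}", window_index=k))
        out.append(make_window([0.6] * 30, label=1, record_id=f"b{k}", window_index=k))
    return out
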