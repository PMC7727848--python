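import numpy as np
import pytest

from chanwise import RawRecording, WindowingParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return WindowingParams(L=2, K=8, N=10)


@pytest.fixture
def recording(rng):
    """A small 4-channel, 400-sample recording of white noise at 100 Hz."""
    return RawRecording(
        data=rng.standard_normal((4, 400)),
        rate=100.0,
        channel_names=("Fp1", "Fp2", "Oz", "Pz"),
        subject_id="s00",
        trial_id="t0",
    )


def brute_force_pearson(x, y):
    """Textbook Pearson oracle with explicit cov/sigma loops.

    Deliberately independent of the package implementation.
    """
    k = len(x)
    mx = sum(x) / k
    my = sum(y) / k
    cov = 0.0
    vx = 0.0
    vy = 0.0
    for a, b in zip(x, y):
        cov += (a - mx) * (b - my)
        vx += (a - mx) ** 2
        vy += (b - my) ** 2
    return cov / (vx**0.5 * vy**0.5)
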