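import numpy as np
import pytest

from wingbeat import DetectionConfig, SignalTrack

FS = 19200.0  # desk-scale working rate: integer divisor of the 192 kHz capture rate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fs():
    return FS


def make_burst_track(
    fs=FS,
    f0=130.0,
    burst_s=0.2,
    starts_s=(0.3,),
    total_s=1.0,
    burst_amp=0.4,
    noise_sd=0.004,
    seed=0,
):
    """A track of white noise with one or more pure-tone tapered bursts."""
    from scipy.signal.windows import tukey

    rng = np.random.default_rng(seed)
    n = int(total_s * fs)
    sig = rng.normal(0, noise_sd, n)
    nb = int(burst_s * fs)
    t = np.arange(nb) / fs
    burst = burst_amp * np.sin(2 * np.pi * f0 * t) * tukey(nb, 0.3)
    for s in starts_s:
        i = int(s * fs)
        sig[i : i + nb] += burst
    return SignalTrack(np.clip(sig, -1, 1), fs, origin="burst-fixture")


@pytest.fixture
def burst_track():
    return make_burst_track()


@pytest.fixture
def det_config():
    return DetectionConfig(threshold=0.02)
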