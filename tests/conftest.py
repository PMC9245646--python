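import numpy as np
import pytest

from soflow import io as sio
from soflow import simulate as sim


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_subject():
    """One 5-minute synthetic subject shared by read-only tests."""
    cfg = sim.SimulationConfig(duration_s=300.0, seed=7)
    rec, gt = sim.simulate_subject(cfg)
    return cfg, rec, gt


@pytest.fixture()
def quiet_recording():
    """A 300-s N2 recording of near-zero background (for planting events)."""
    fs = 256.0
    n = int(300 * fs)
    rng = np.random.default_rng(11)
    data = rng.normal(0.0, 1.0, (22, n))
    from soflow.channels import MONTAGE_22

    return sio.Recording(data=data, fs=fs, channel_labels=list(MONTAGE_22),
                         stages=["N2"] * 10)
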