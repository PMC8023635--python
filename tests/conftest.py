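import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from comanet.eeg_io import Montage, load_montage

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ld_montage() -> Montage:
    return load_montage("ld1020")


@pytest.fixture(scope="session")
def hd_montage() -> Montage:
    return load_montage("hd91")


def ring_montage(n: int = 8) -> Montage:
    """n electrodes evenly spaced on the head's equator (unit radius)."""
    theta = 2 * np.pi * np.arange(n) / n
    coords = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])
    return Montage(name=f"ring{n}", labels=[f"S{i}" for i in range(n)],
                   coordinates=coords)


@pytest.fixture(scope="session")
def ring8() -> Montage:
    return ring_montage(8)


@pytest.fixture(scope="session")
def ring10() -> Montage:
    return ring_montage(10)
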