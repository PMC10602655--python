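import numpy as np
import pytest

from eegfc.layout import default_layout, generic_layout
from eegfc.preprocessing import Epoch
from eegfc.synth import simulate_dataset


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def small_dataset():
    """A small three-group dataset with a visible coupling effect."""
    return simulate_dataset(3, 3, effect_size=0.3, seed=7)


def make_epoch(data: np.ndarray, fs: float = 500.0, subject: str = "S",
               index: int = 0, group: str = "HC") -> Epoch:
    return Epoch(data=np.atleast_2d(np.asarray(data, dtype=float)), fs=fs,
                 source_subject=subject, index=index, group_label=group)


@pytest.fixture
def toy_epoch():
    """Three channels of 2 s structured toy signal at 500 Hz."""
    t = np.arange(1000) / 500.0
    rng = np.random.default_rng(42)
    x0 = np.cos(2 * np.pi * 10 * t) + 0.1 * rng.standard_normal(1000)
    x1 = np.cos(2 * np.pi * 10 * t - 0.8) + 0.1 * rng.standard_normal(1000)
    x2 = rng.standard_normal(1000)
    return make_epoch(np.vstack([x0, x1, x2]))
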