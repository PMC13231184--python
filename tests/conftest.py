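import numpy as np
import pytest

from pavasc import synthetic as syn
from pavasc.core import Volume3D


@pytest.fixture(scope="session")
def flat_phantom() -> syn.PhantomSpec:
    """Noiseless flat-interface phantom with three horizontal vessels."""
    return syn.default_phantom()


@pytest.fixture(scope="session")
def noisy_phantom() -> syn.PhantomSpec:
    """Same geometry with 5%-of-contrast US noise."""
    return syn.default_phantom(noise_us=0.05)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def small_volume() -> Volume3D:
    values = np.arange(4 * 5 * 6, dtype=float).reshape(4, 5, 6)
    return Volume3D(values, (0.1, 0.1, 0.1), "US")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / float(denom) if denom else 1.0
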