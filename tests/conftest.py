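import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles importable

from fluidconn.static import ConnectivityGraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_graph(n: int, rng, density: float = 1.0) -> ConnectivityGraph:
    """Random symmetric weighted graph with weights in (0, 1)."""
    w = rng.uniform(0.05, 1.0, size=(n, n))
    w = (w + w.T) / 2
    if density < 1.0:
        mask = rng.random((n, n)) < density
        mask = mask | mask.T
        w = w * mask
    np.fill_diagonal(w, 0.0)
    return ConnectivityGraph(weights=w)


@pytest.fixture
def graph_factory():
    return random_graph


def comb_signal(
    fs: float = 128.0, duration: float = 12.0, n_regions: int = 6
) -> "np.ndarray":
    """Strictly periodic multi-tone signal whose sliding windows repeat
    exactly at 1 s steps: every tone frequency is an odd integer (so a 1.5 s
    window never spans a whole number of cycles and circular means stay
    well-defined), regions differ in frequency and phase offset."""
    t = np.arange(int(duration * fs)) / fs
    delta_f = [1, 3]
    alpha_f = [7, 9, 11]
    beta_f = [13, 17, 21, 25, 29, 15]
    data = np.empty((n_regions, t.size))
    for r in range(n_regions):
        theta = 0.7 * r
        data[r] = (
            np.cos(2 * np.pi * delta_f[r % len(delta_f)] * t + theta)
            + 0.8 * np.cos(2 * np.pi * 5 * t + 1.3 * theta)
            + 0.6 * np.cos(2 * np.pi * alpha_f[r % len(alpha_f)] * t + 0.9 * theta)
            + 0.4 * np.cos(2 * np.pi * beta_f[r % len(beta_f)] * t + 1.7 * theta)
        )
    return data
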