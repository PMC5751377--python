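import numpy as np
import pytest

from anomdiff.observables import TimeSeries, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def random_series(rng):
    """Factory for random uniform-grid series of a given length."""

    def make(n: int, dt: float = 1.0, seed: int | None = None) -> TimeSeries:
        r = rng if seed is None else np.random.default_rng(seed)
        return TimeSeries(np.arange(n) * dt, r.standard_normal(n))

    return make


@pytest.fixture
def small_trajectory(rng):
    """8 frames x 5 atoms of Gaussian coordinates, two chains."""
    coords = rng.standard_normal((8, 5, 3))
    chain_ids = np.array(["A", "A", "A", "B", "B"], dtype=object)
    return Trajectory(coords, frame_dt=0.5, chain_ids=chain_ids)
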