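import numpy as np
import pytest

from ecdnasim import SimulationConfig, TumorState, run_to_size


@pytest.fixture(scope="session")
def tumor_q5():
    """A moderately constrained selected tumor reused by read-only tests."""
    return run_to_size(SimulationConfig(k=20, s=1.0, q=5, n_final=3000, seed=101))


@pytest.fixture(scope="session")
def disc_state():
    """Radially symmetric synthetic tumor: fully occupied disc of radius 30
    centered on the founder, uniform 5 copies per cell."""
    r = 30
    coords = [(x, y) for x in range(-r, r + 1) for y in range(-r, r + 1)
              if x * x + y * y <= r * r]
    xs = np.array([c[0] for c in coords])
    ys = np.array([c[1] for c in coords])
    return TumorState(xs, ys, np.full(len(xs), 5))


@pytest.fixture(scope="session")
def indexed_disc_state():
    """Disc tumor whose copy counts equal the cell index (all distinct), so
    subsampling without replacement is directly observable."""
    r = 20
    coords = [(x, y) for x in range(-r, r + 1) for y in range(-r, r + 1)
              if x * x + y * y <= r * r]
    xs = np.array([c[0] for c in coords])
    ys = np.array([c[1] for c in coords])
    return TumorState(xs, ys, np.arange(len(xs)))
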