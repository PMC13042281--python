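import numpy as np
import pytest

import velostream as vs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sink_dataset():
    """400 cells around a noiseless linear sink at the box center."""
    return vs.make_field_dataset(
        vs.FixtureSpec(n_cells=400, field_kind="linear-sink", noise_sd=0.0, seed=7)
    )


@pytest.fixture
def uniform_dataset():
    return vs.make_field_dataset(
        vs.FixtureSpec(n_cells=200, field_kind="uniform", noise_sd=0.0, seed=3)
    )


@pytest.fixture
def sink_field(sink_dataset):
    grid = vs.build_grid(sink_dataset.coords, 12, 0.05)
    return vs.average_velocities(sink_dataset, grid)


def analytic_sink_field(center, lo=0.0, hi=10.0, resolution=12, scale=1.0):
    """Grid field with node vectors set exactly to v(x) = -(x - center)."""
    center = np.asarray(center, dtype=float)
    corners = np.array([[lo] * 3, [hi] * 3])
    grid = vs.build_grid(corners, resolution, 0.0, scale=scale)
    return vs.field_from_function(grid, lambda p: center - p)
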