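import numpy as np
import pytest

from dunefire import DuneSpec, GridSpec, generate_landscape


@pytest.fixture(scope="session")
def default_landscape():
    """The packaged 37-dune configuration, generated once per session."""
    return generate_landscape(rng_seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_dune_landscape():
    """Two small dunes on a compact grid, close enough for bird dispersal."""
    table = [
        DuneSpec(1, 4, True, "low"),
        DuneSpec(2, 4, True, "low"),
    ]
    grid = GridSpec(width_m=2000, height_m=2000, cell_m=100)
    return generate_landscape(table, grid, rng_seed=5)
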