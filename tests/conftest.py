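import numpy as np
import pytest

import grassbird as gb


@pytest.fixture(scope="session")
def default_cfg() -> gb.RunConfig:
    return gb.load_config()


@pytest.fixture
def uniform_landscape():
    """Factory for single-cover landscapes of a given role and size."""

    def make(cover, n_rows=10, n_cols=10, role=gb.LandscapeRole.BREEDING):
        grid = np.full((n_rows, n_cols), int(cover), dtype=np.int8)
        return gb.Landscape(grid=grid, role=role)

    return make


@pytest.fixture
def random_landscape():
    """Factory for seeded random landscapes."""

    def make(p=(1 / 3, 1 / 3, 1 / 3), n_rows=12, n_cols=12,
             role=gb.LandscapeRole.BREEDING, seed=0):
        dist = gb.CoverDistribution(*p)
        return gb.generate_landscape(
            dist, n_rows=n_rows, n_cols=n_cols, role=role, seed=seed
        )

    return make
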