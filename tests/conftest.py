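import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phytoreg import gridding, synthetic

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def landscape():
    """Default 12x12 two-district landscape."""
    return synthetic.generate_landscape(synthetic.LandscapeSpec(), seed=1)


@pytest.fixture(scope="session")
def community():
    return synthetic.CommunitySpec(seed=2)


@pytest.fixture(scope="session")
def records(landscape, community):
    return synthetic.generate_occurrences(landscape, community)


@pytest.fixture(scope="session")
def grid(landscape):
    return gridding.GridSpec(origin=landscape.origin, cell_size=landscape.spec.cell_size)


@pytest.fixture(scope="session")
def cell_table(records, grid):
    """Gridded, filtered default synthetic dataset."""
    curated, _ = gridding.curate_records(
        records, lon_col="decimalLongitude", lat_col="decimalLatitude"
    )
    table = gridding.assign_to_grid(curated, grid)
    return gridding.filter_and_merge(table, min_records=5)


@pytest.fixture(scope="session")
def incidence(cell_table):
    return gridding.incidence_matrix(cell_table)


def random_incidence(rng: np.random.Generator, n_cells: int, n_species: int) -> pd.DataFrame:
    """Random presence/absence matrix guaranteed free of empty cells and
    empty species columns."""
    M = (rng.random((n_cells, n_species)) < 0.3).astype(int)
    for i in range(n_cells):
        if M[i].sum() == 0:
            M[i, rng.integers(n_species)] = 1
    keep = M.sum(axis=0) > 0
    M = M[:, keep]
    return pd.DataFrame(
        M,
        index=[f"c{i:03d}" for i in range(n_cells)],
        columns=[f"sp{j:03d}" for j in range(M.shape[1])],
    )
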