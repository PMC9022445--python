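import numpy as np
import pandas as pd
import pytest

from pamkit.ingest import CountMatrix, Recording, Site
from pamkit.simulate import CommunitySpec, SpeciesSpec, simulate_counts


@pytest.fixture
def toy_count_matrix():
    counts = pd.DataFrame(
        [[4, 0, 9], [1, 2, 0], [0, 0, 16], [3, 5, 1]],
        index=["r1", "r2", "r3", "r4"],
        columns=["AAA", "BBB", "CCC"],
    )
    return CountMatrix(counts, {"AAA": "bird", "BBB": "bird", "CCC": "mammal"})


@pytest.fixture
def toy_recordings():
    return [
        Recording("r1", "s1", "2018-06-01", year=2018),
        Recording("r2", "s1", "2018-06-02", year=2018),
        Recording("r3", "s2", "2018-06-01", year=2018),
        Recording("r4", "s2", "2018-06-02", year=2018),
    ]


@pytest.fixture
def square_sites():
    # ~1 km square
    return [
        Site("s1", 44.0, -71.0),
        Site("s2", 44.009, -71.0),
        Site("s3", 44.0, -71.0125),
        Site("s4", 44.009, -71.0125),
    ]


@pytest.fixture(scope="session")
def default_sim():
    """One seeded draw from the default community model, shared across tests."""
    return simulate_counts(CommunitySpec(), seed=20180513)


def single_species_spec(**overrides) -> CommunitySpec:
    """A one-species community isolating the spatial day-effect structure."""
    defaults = dict(
        species=[SpeciesSpec("FOC", fixed_baseline=25.0)],
        day_effect_sd=0.7,
        spatial_range_m=500.0,
        regional_sd=0.0,
        guild_sd=0.0,
        residual_sd=0.5,
    )
    defaults.update(overrides)
    return CommunitySpec(**defaults)
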