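import numpy as np
import pandas as pd
import pytest

import biogaps as bg
from biogaps.overlay import SpeciesRange


@pytest.fixture(scope="session")
def grid8():
    return bg.build_grid(8, 8, 4)


@pytest.fixture(scope="session")
def toy_world(grid8):
    """Hand-built 8x8 world: 3 species, 2 countries, awkward records.

    Records include an interior-boundary point, an out-of-extent point and
    a record of a species outside its range.
    """
    ranges = [
        SpeciesRange("sp_a", "birds", frozenset({0, 1, 8, 9})),  # 2x2 block at origin
        SpeciesRange("sp_b", "birds", frozenset({9, 10, 17})),
        SpeciesRange("sp_c", "mammals", frozenset({63})),  # single-cell endemic
    ]
    records = pd.DataFrame(
        {
            "record_id": [f"r{i}" for i in range(8)],
            "species_id": ["sp_a", "sp_a", "sp_b", "sp_b", "sp_c", "sp_a", "sp_b", "sp_c"],
            "x": [0.5, 1.0, 2.5, 1.2, 7.5, 0.2, 6.0, 9.5],
            #      c0   c1   c2*  c9   c63  c0   c?   outside
            "y": [0.5, 0.0, 2.5, 1.7, 7.5, 0.4, 5.0, 2.0],
            "publisher_id": ["p0", "p0", "p1", "p1", "p0", "p1", "p0", "p0"],
        }
    )
    # r2: sp_b at cell (2,2)=18, outside sp_b's range -> unexpected
    # r6: sp_b at cell (6,5)=46, outside range -> unexpected
    # r7: x=9.5 outside the 8-wide extent -> invalid
    country = np.array(["east" if (i % 8) >= 4 else "west" for i in range(64)])
    return {"ranges": ranges, "records": records, "country": country, "grid": grid8}


@pytest.fixture(scope="session")
def small_world():
    """Seeded generated 16x16 world, small enough for brute-force oracles."""
    cfg = bg.WorldConfig(
        extent=(16, 16),
        n_species={"birds": 25, "mammals": 12, "amphibians": 13},
        range_size_distribution=(12.0, 1.0),
        n_publishers=6,
        n_countries=4,
        n_airports=5,
        n_records=4000,
        seed=42,
    )
    return bg.generate_world(cfg)


@pytest.fixture(scope="session")
def demo_world():
    """Default-condition 32x32 world used by the heavier integration tests."""
    return bg.generate_world(bg.WorldConfig(n_records=20_000, seed=7))


@pytest.fixture(scope="session")
def demo_analysis(demo_world):
    return bg.analyze_world(demo_world)


def world_as_oracle_inputs(world):
    """Convert package structures to the plain dict/list forms the oracles eat."""
    ranges = {r.species_id: set(r.cells) for r in world.ranges}
    records = list(
        zip(world.records["species_id"], world.records["x"], world.records["y"])
    )
    return ranges, records
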