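import numpy as np
import pandas as pd
import pytest

from scalepart import (
    EnvironmentalLayer,
    LandscapeConfig,
    generate_landscape,
    generate_species_pool,
    sample_occurrences,
)


@pytest.fixture(scope="session")
def small_config():
    """A small landscape used by most generator-dependent tests."""
    return LandscapeConfig(width_px=96, height_px=96, patch_scale=6.0, seed=7)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_community(small_config, small_landscape):
    """Occurrence records of a climate-structured community on the small landscape."""
    niches = generate_species_pool(
        12, {"climate": 1.0, "lulc": 1.0}, small_landscape, seed=3
    )
    return sample_occurrences(small_landscape, niches, 20000, seed=5)


def make_records(rows):
    """Build an occurrence-record frame from (species, lon_text, lat_text) tuples."""
    return pd.DataFrame(
        {
            "species_id": [r[0] for r in rows],
            "lon": [float(r[1]) for r in rows],
            "lat": [float(r[2]) for r in rows],
            "lon_text": [r[1] for r in rows],
            "lat_text": [r[2] for r in rows],
        }
    )


def random_count_matrix(rng, max_rows=20, max_cols=15, high=9):
    """Random count matrix with no zero row or column (for inertia oracles)."""
    while True:
        n = rng.integers(3, max_rows + 1)
        m = rng.integers(3, max_cols + 1)
        Y = rng.integers(0, high, size=(n, m)).astype(float)
        if (Y.sum(axis=1) > 0).all() and (Y.sum(axis=0) > 0).all():
            return Y


def constant_layer(value, n=8, cell_area=1.0, name="flat", kind="continuous"):
    return EnvironmentalLayer(
        name=name, kind=kind, grid=np.full((n, n), value), cell_area=cell_area
    )
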