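import numpy as np
import pytest

from treatscan.raster_core import Grid, MultibandRaster
from treatscan.synthetic_scenes import SceneSpec, generate_scene


def make_raster(values, cell_size=10.0, names=None, origin=(0.0, 1000.0),
                crs="EPSG:32610"):
    """Small raster helper used throughout the suite."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[None]
    grid = Grid(origin[0], origin[1], cell_size, values.shape[1],
                values.shape[2], crs)
    names = names or [f"b{i + 1}" for i in range(values.shape[0])]
    return MultibandRaster(grid, names, values)


@pytest.fixture(scope="session")
def small_scene():
    """A compact scene with every footprint kind, shared across tests."""
    spec = SceneSpec(seed=11, n_rows=160, n_cols=160, n_clearcut=2,
                     n_thinning=2, n_fire=2, n_confuser=2, n_wildfire=1,
                     min_footprint_ha=2.0, max_footprint_ha=4.0)
    return generate_scene(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
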