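import numpy as np
import pytest

from phckit.covariates import build_stack
from phckit.landscape import (
    LandscapeConfig,
    TrueSuitability,
    generate_landcover,
    generate_terrain,
    generate_transects,
    place_features,
    sample_occurrences,
)
from phckit.raster import RasterGrid


@pytest.fixture(scope="session")
def small_config():
    """A compact landscape for fast unit tests (18 km x 18 km)."""
    return LandscapeConfig(
        grid_rows=60,
        grid_cols=60,
        n_populations=2,
        n_transects=40,
        n_presences=50,
        pseudo_absence_min_distance_m=1000.0,
        patch_radius_cells=3,
        random_seed=11,
    )


@pytest.fixture(scope="session")
def small_landscape(small_config):
    cfg = small_config
    elev = generate_terrain(cfg)
    lc = generate_landcover(cfg, elev)
    feats = place_features(cfg, elev)
    stack = build_stack(elev, lc, feats)
    truth = TrueSuitability().evaluate(stack)
    transects = generate_transects(cfg, elev)
    occ = sample_occurrences(truth, transects, cfg)
    return {
        "config": cfg,
        "elevation": elev,
        "landcover": lc,
        "features": feats,
        "stack": stack,
        "truth": truth,
        "transects": transects,
        "occurrences": occ,
    }


@pytest.fixture()
def uniform_raster():
    return RasterGrid(np.ones((5, 5)), cell_size_m=100.0)
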