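import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cumimpact import (
    Grid,
    HabitatLayer,
    NormalizedLayer,
    Raster,
    SeascapeConfig,
    VulnerabilityMatrix,
)
from cumimpact.synthetic import generate_seascape

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def grid():
    return Grid(n_rows=6, n_cols=8, cell_size=1000.0)


@pytest.fixture
def small_config():
    return SeascapeConfig(n_rows=30, n_cols=30, seed=11)


@pytest.fixture(scope="session")
def seascape():
    """One moderately sized synthetic seascape shared across tests."""
    return generate_seascape(SeascapeConfig(n_rows=40, n_cols=40, seed=7))


def random_instance(seed, max_side=32, max_habitats=6, max_stressors=8, nodata_frac=0.05):
    """Random small impact-model instance: normalized layers, habitat stack, weights.

    Constructed directly (not via the seascape generator) so the oracle
    cross-check covers arbitrary presence/nodata patterns, including cells
    with zero habitats.
    """
    rng = np.random.default_rng(seed)
    rows = int(rng.integers(4, max_side + 1))
    cols = int(rng.integers(4, max_side + 1))
    n_hab = int(rng.integers(1, max_habitats + 1))
    n_str = int(rng.integers(1, max_stressors + 1))
    g = Grid(n_rows=rows, n_cols=cols, cell_size=1.0)

    def sprinkle_nodata(v):
        mask = rng.random(v.shape) < nodata_frac
        v = v.astype(float)
        v[mask] = np.nan
        return v

    stressors = [
        NormalizedLayer(f"s{j}", "t1", Raster(g, sprinkle_nodata(rng.random((rows, cols))), "normalized"), 1.0)
        for j in range(n_str)
    ]
    habitats = [
        HabitatLayer(
            f"h{i}",
            "nearshore_mixed",
            Raster(g, sprinkle_nodata((rng.random((rows, cols)) < 0.6).astype(float)), "presence"),
        )
        for i in range(n_hab)
    ]
    weights = VulnerabilityMatrix.from_arrays(
        [f"h{i}" for i in range(n_hab)],
        [f"s{j}" for j in range(n_str)],
        rng.uniform(0, 4, size=(n_hab, n_str)),
    )
    return stressors, habitats, weights
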