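import numpy as np
import pytest

from catena.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def tiny_config(**kw) -> SimulationConfig:
    defaults = dict(n_young=6, n_old=6, grid_shape=(16, 16, 16), seed=7)
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(tiny_config())


def micro_geometry(grid_shape=(10, 10, 10)):
    """Minimal disjoint ROI geometry for very small test grids."""

    def block(x0, x1, y0, y1, z0, z1):
        xs, ys, zs = np.meshgrid(
            np.arange(x0, x1), np.arange(y0, y1), np.arange(z0, z1),
            indexing="ij",
        )
        return np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)

    return {
        "lc_left": block(1, 2, 6, 8, 3, 6),
        "lc_right": block(4, 5, 6, 8, 3, 6),
        "snvta_left": block(1, 3, 1, 3, 6, 8),
        "snvta_right": block(4, 6, 1, 3, 6, 8),
        "pons_ref": block(2, 4, 4, 5, 3, 6),
        "crus_ref": block(2, 4, 0, 1, 6, 8),
        "ventricle": block(1, 5, 7, 9, 4, 5),
    }


def micro_config(**kw) -> SimulationConfig:
    defaults = dict(
        n_young=4, n_old=4, grid_shape=(10, 10, 10),
        roi_geometry=micro_geometry(), seed=3,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)
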