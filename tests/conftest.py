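import numpy as np
import pytest
from hypothesis import settings

from sgascreen import TruthConfig, make_grid, simulate_screen

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_plate(rng, n_rows=16, n_cols=24, absent_frac=0.05, sigma=0.3,
                 **meta):
    """A random positive-size plate with some absent positions.

    Sizes are rounded to 2 decimals, like rendered pixel areas, so they
    survive serialization exactly.
    """
    size = np.round(rng.lognormal(np.log(400.0), sigma, (n_rows, n_cols)), 2)
    absent = rng.random((n_rows, n_cols)) < absent_frac
    size[absent] = 0.0
    return make_grid(size, **meta)


NOISELESS = dict(
    gene_fitness_sigma=0.0, row_sigma=0.0, col_sigma=0.0,
    gradient_amplitude=0.0, edge_boost=1.0, noise_sigma=0.0,
    dropout_rate=0.0, small_rate=0.0,
)


@pytest.fixture(scope="session")
def noiseless_screen():
    """Small noiseless screen: 96 genes, 16x24 plates, 1 condition."""
    return simulate_screen(
        n_genes=96, plate_format=(16, 24), n_reps=2,
        conditions=("untreated",),
        truth_config=TruthConfig(effect_fraction=0.1, effect_size=1.0,
                                 **NOISELESS),
        seed=7,
    )
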