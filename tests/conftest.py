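import numpy as np
import pandas as pd
import pytest

from nirmc.spectra import SpectraSet, WavelengthGrid


def make_set(X, sample_ids=None, species=None, origins=None, replicates=None,
             roles=None, grid=None, mc=None):
    """Build a small SpectraSet with sensible metadata defaults."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if grid is None:
        grid = WavelengthGrid(np.linspace(1000.0, 2500.0, X.shape[1]))
    meta = pd.DataFrame({
        "sample_id": sample_ids or [f"S{i:02d}" for i in range(n)],
        "species": species or ["Arabica"] * n,
        "origin": origins or ["Aceh"] * n,
        "replicate": replicates or [1] * n,
        "role": roles or ["unassigned"] * n,
    })
    return SpectraSet(grid, X, meta, mc)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return WavelengthGrid(np.linspace(1100.0, 2400.0, 40))


@pytest.fixture
def default_dataset():
    """One default synthetic dataset (replicate spectra + weighings)."""
    from nirmc.simulate import make_default_config, simulate_dataset

    return simulate_dataset(make_default_config(), seed=7)
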