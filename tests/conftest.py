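import numpy as np
import pytest

from markertime import (
    PriorSettings,
    SimulationConfig,
    compute_size_factors,
    fit_vi,
    normalize_expression,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Mixed-behaviour simulated dataset, normalized, with ground truth."""
    ds = simulate_dataset(SimulationConfig(n_cells=40, n_genes=6,
                                           frac_switch=0.5, seed=11))
    Yn = normalize_expression(ds.Y, compute_size_factors(ds.Y))
    return ds, Yn


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A quick variational fit on the small dataset (correct behaviours)."""
    ds, Yn = small_dataset
    return fit_vi(Yn, ds.true_behaviours, PriorSettings(), steps=1500,
                  n_draws=400, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
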