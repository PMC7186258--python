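import numpy as np
import pytest

from lvgvar.estimation import MomentData
from lvgvar.io import timeseries_moments
from lvgvar.simulate import (
    _blank_estimation_spec,
    simulate_panel,
    simulate_ts,
    small_panel_model,
    small_ts_model,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def ts_truth():
    return small_ts_model()


@pytest.fixture(scope="session")
def panel_truth():
    return small_panel_model()


@pytest.fixture(scope="session")
def ts_dataset(ts_truth):
    return simulate_ts(ts_truth, n_occasions=400, seed=101)


@pytest.fixture(scope="session")
def ts_data(ts_dataset):
    """Complete-pair moments from the simulated series (ML layout)."""
    return timeseries_moments(ts_dataset, method="ml")


@pytest.fixture(scope="session")
def panel_dataset(panel_truth):
    return simulate_panel(panel_truth, n_subjects=600, seed=102)


@pytest.fixture(scope="session")
def panel_data(panel_dataset):
    return MomentData.from_dataframe(panel_dataset.frame)


@pytest.fixture(scope="session")
def ts_blank(ts_truth):
    return _blank_estimation_spec(ts_truth)


@pytest.fixture(scope="session")
def panel_blank(panel_truth):
    return _blank_estimation_spec(panel_truth)


def random_network(rng, p, density=0.5, max_partial=0.35):
    """Random valid GGM: sparse partials rescaled until (I - Omega) is PD."""
    from lvgvar.networks import GaussianNetwork

    while True:
        omega = np.zeros((p, p))
        for i in range(p):
            for j in range(i):
                if rng.random() < density:
                    omega[i, j] = omega[j, i] = rng.uniform(-max_partial, max_partial)
        if np.linalg.eigvalsh(np.eye(p) - omega)[0] > 0.05:
            delta = rng.uniform(0.5, 2.0, size=p)
            return GaussianNetwork(omega=omega, delta=delta)


def random_stable_beta(rng, p, target_radius=0.7):
    b = rng.normal(scale=0.5, size=(p, p))
    radius = np.max(np.abs(np.linalg.eigvals(b)))
    return b * (target_radius / max(radius, 1e-9)) * rng.uniform(0.5, 1.0)
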