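"""Shared fixtures.  Expensive MCMC fits are session-scoped and reused."""

import numpy as np
import pytest

from painseq.fit import HierarchicalObserverModel, SamplerConfig
from painseq.recovery import simulate_dataset


@pytest.fixture(scope="session")
def ekf_sim():
    """12 synthetic subjects x 80 trials simulated from the eKF."""
    return simulate_dataset("ekf", n_subjects=12, seed=11)


@pytest.fixture(scope="session")
def ekf_desk_fit(ekf_sim):
    """Hierarchical eKF fit at full desk scale (4 chains x 1000/1000)."""
    model = HierarchicalObserverModel.from_dataframe(ekf_sim["data"], model="ekf")
    return model.fit(SamplerConfig.desk_scale(seed=5))


@pytest.fixture(scope="session")
def kf_fit_on_ekf_data(ekf_sim):
    """KF fit to the same eKF-simulated data (for comparison tests)."""
    model = HierarchicalObserverModel.from_dataframe(ekf_sim["data"], model="kf")
    return model.fit(SamplerConfig(chains=2, warmup=400, draws=400, seed=6))


@pytest.fixture(scope="session")
def strong_weighting_sim():
    """Data simulated from the eKF with strong expectation weighting
    (large subjective noise eps, low stochasticity and response noise)."""
    group = {"eps": (2.9, 0.2), "s": (1.6, 0.2), "xi": (1.1, 0.2)}
    return simulate_dataset("ekf", n_subjects=8, seed=21, group_params=group)


@pytest.fixture(scope="session")
def strong_weighting_fits(strong_weighting_sim):
    cfg = SamplerConfig(chains=2, warmup=400, draws=400, seed=9)
    fits = []
    for mid in ("ekf", "kf"):
        model = HierarchicalObserverModel.from_dataframe(
            strong_weighting_sim["data"], model=mid)
        fits.append(model.fit(cfg))
    return fits


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
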