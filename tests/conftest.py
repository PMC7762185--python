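import numpy as np
import pytest

from rbemap import LQFit, TruthModel, make_scenario, simulate_counts


@pytest.fixture
def make_fit():
    """Factory for LQFit objects with optional covariance/metadata."""

    def _make(alpha, beta, cov=None, **meta):
        return LQFit(
            alpha=alpha,
            beta=beta,
            covariance=np.zeros((2, 2)) if cov is None else np.asarray(cov, float),
            pe=0.5,
            cells_seeded=100,
            log_likelihood=0.0,
            deviance=0.0,
            n_points=0,
            **meta,
        )

    return _make


@pytest.fixture
def photon_reference(make_fit):
    """The documented synthetic photon reference curve."""
    return make_fit(0.2, 0.02, ion="photon")


@pytest.fixture(scope="session")
def carbon_experiment():
    """One seeded synthetic carbon-beam experiment at the assay's design
    (12 columns, 5 exposure levels, 2 plates/level, 100 cells/well)."""
    scenario = make_scenario("carbon")
    truth = TruthModel()
    return simulate_counts(scenario, truth, seed=20260924), truth
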