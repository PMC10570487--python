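import numpy as np
import pytest

from ibsync.connectivity import CANONICAL_BANDS, analytic_band
from ibsync.preprocess import preprocess_recording
from ibsync.simulate import Coupling, OscBand, SimConfig, simulate_dyad

THETA_BANDS = (OscBand("theta", 4.0, 7.0, 6.0),)


@pytest.fixture(scope="session")
def coupled_config():
    """Small theta-coupled dyad: cooperation-only, 16 trials, sigma = 0.5."""
    return SimConfig(
        n_dyads=2,
        n_trials_per_mode=16,
        modes=("cooperation",),
        bands=THETA_BANDS,
        coupling={"theta": {"cooperation": Coupling(0.5, 0.5)}},
        noise_sd=0.0,
        simulate_gaze=False,
        seed=11,
    )


@pytest.fixture(scope="session")
def coupled_dyad(coupled_config):
    return simulate_dyad(coupled_config, 0)


@pytest.fixture(scope="session")
def coupled_epochs(coupled_dyad):
    rec, _ = coupled_dyad
    return preprocess_recording(rec)


@pytest.fixture(scope="session")
def coupled_tensors(coupled_epochs):
    ep_a, ep_b = coupled_epochs
    band = CANONICAL_BANDS["theta"]
    return analytic_band(ep_a, band), analytic_band(ep_b, band)


@pytest.fixture(scope="session")
def full_dyad():
    """One dyad with gaze and all three modes, small trial count."""
    cfg = SimConfig(
        n_dyads=1,
        n_trials_per_mode=6,
        bands=THETA_BANDS,
        coupling={"theta": {"cooperation": Coupling(1.1, 0.5)}},
        noise_sd=1.0,
        seed=21,
    )
    return simulate_dyad(cfg, 0), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
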