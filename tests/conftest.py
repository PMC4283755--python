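import numpy as np
import pytest

from seamsel import EndpointModel, SimSeed, TrialDesign, simulate_stage1


@pytest.fixture
def null_model():
    """Three experimental arms, all effects zero, unit SDs, rho_w = 0.5."""
    return EndpointModel(
        mu_b=np.zeros(4), mu_B=np.zeros(4), sigma0=1.0, sigma=1.0, rho_w=0.5
    )


@pytest.fixture
def std_design():
    """The standard simulation design: k=3, n1=4, N1=32, n2=64, alpha=0.025."""
    return TrialDesign(k=3, N1=32, n1=4, n2=64)


@pytest.fixture
def effects_model():
    """Arm 1 best on both endpoints, halves/quarters for arms 2-3."""
    return EndpointModel(
        mu_b=np.array([0.0, 0.2, 0.1, 0.05]),
        mu_B=np.array([0.0, 0.3, 0.15, 0.075]),
        sigma0=1.0,
        sigma=1.0,
        rho_w=0.5,
    )


@pytest.fixture
def small_trial(null_model, std_design):
    """One simulated stage-1 dataset at the standard sizes."""
    return simulate_stage1(null_model, std_design, SimSeed(7, 0))
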