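import numpy as np
import pytest

from ivim3fit import BValueScheme, SimConfig, TriParams, simulate_batch


@pytest.fixture(scope="session")
def bscheme() -> BValueScheme:
    return BValueScheme.default_scheme()


@pytest.fixture(scope="session")
def interior_tri_params() -> TriParams:
    """A truth set interior to both the simulator ranges and the fit bounds."""
    return TriParams(S0=1.0, D=1.5e-3, D1star=0.03, D2star=1.0, f1=0.2, f2=0.1)


@pytest.fixture(scope="session")
def noiseless_batch():
    cfg = SimConfig(n_curves=50, snr_spec="noiseless", seed=7)
    return simulate_batch(cfg)


@pytest.fixture(scope="session")
def noisy_batch_snr15():
    cfg = SimConfig(n_curves=200, snr_spec=15, seed=8)
    return simulate_batch(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
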