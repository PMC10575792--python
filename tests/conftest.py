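import numpy as np
import pytest

from casyn.model import ModelParams


@pytest.fixture
def params() -> ModelParams:
    """Literature kinetic constants with explicit (B, mu, lam) defaults.

    mu*R*tau_b = 200 at R = 20 Hz sets the scale on which buffer sizes are
    interesting; lam = 1 puts the drive-free free-calcium level c* =
    mu*R*tau_c = 2 in the responsive part of the release sigmoid.
    """
    return ModelParams(B=200.0, mu=0.001, lam=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_valid_params(rng: np.random.Generator) -> ModelParams:
    """Random draw over the physiological regime (B, mu, lam sampled)."""
    return ModelParams(
        B=float(rng.uniform(10.0, 1000.0)),
        mu=float(10.0 ** rng.uniform(-4, -2)),
        lam=float(10.0 ** rng.uniform(-1, 1)),
    )
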