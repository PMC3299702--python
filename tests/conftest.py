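import numpy as np
import pytest

from dispersalfit import KernelTruth, default_design, gen_settlement


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def power_truth():
    """Power-law generating truth: moderate overdispersion, per-station
    confirmation probabilities at their survey defaults."""
    return KernelTruth(family="power", intercept=4.3, slope=-0.31, dispersion=2.0)


@pytest.fixture(scope="session")
def exp_truth():
    return KernelTruth(family="exponential", intercept=6.3, slope=-0.04, dispersion=2.0)


@pytest.fixture(scope="session")
def settlement(design, power_truth):
    return gen_settlement(design, power_truth, seed=20260930)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
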