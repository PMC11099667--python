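import pytest

from emem.core_model import (
    ErrorDistributionSpec,
    ErrorLaw,
    ErrorStructure,
    Family,
    ProtocolSpec,
    SystematicSpec,
    VarianceScalingSpec,
)
from emem.simulate import (
    BETA,
    ALPHA,
    LAM,
    SIGMA,
    XB,
    SimulationConfig,
    fig1_protocol,
    piecewise_mixture_protocol,
    simulate_dataset,
)

TRUE = {"beta": BETA, "alpha": ALPHA, "lam": LAM, "xb": XB, "sigma": SIGMA}


@pytest.fixture(scope="session")
def reference_protocol():
    """(EMEM, wBH, 1, N) with the reference generating parameters."""
    return fig1_protocol()


@pytest.fixture(scope="session")
def hp_protocol():
    """(EMEM, wBH, hp, NM2) full-complexity generating configuration."""
    return piecewise_mixture_protocol()


@pytest.fixture(scope="session")
def biphasic_data(reference_protocol):
    """Moderate-size draw from the reference biphasic lognormal protocol."""
    return simulate_dataset(
        SimulationConfig(protocol=reference_protocol, n=1500, seed=11)
    )


@pytest.fixture(scope="session")
def hp_data(hp_protocol):
    """Draw from the piecewise-heteroscedastic mixture protocol."""
    return simulate_dataset(SimulationConfig(protocol=hp_protocol, n=2000, seed=13))


@pytest.fixture
def huxley_protocol():
    """Simple Huxley multiplicative-lognormal protocol."""
    return ProtocolSpec(
        error_structure=ErrorStructure.MULTIPLICATIVE,
        systematic=SystematicSpec(family=Family.HUXLEY, beta=BETA, alpha=ALPHA),
        scaling=VarianceScalingSpec(),
        error=ErrorDistributionSpec(law=ErrorLaw.NORMAL, sigma=SIGMA),
    )


@pytest.fixture
def mixture_error():
    """Well-separated two-component zero-mean scale mixture."""
    return ErrorDistributionSpec(
        law=ErrorLaw.NORMAL_MIXTURE, weights=(0.3, 0.7), sds=(0.5, 2.0)
    )
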