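import numpy as np
import pytest

from kiteipm.multistate import MsParams
from kiteipm.simulate import ScenarioConfig, generate


@pytest.fixture(scope="session")
def table_params() -> MsParams:
    """Posterior-mean parameter point of the full integrated model."""
    return MsParams(
        phi=0.808, m_juv=0.428, m_1y=0.764, m_2my=0.764,
        rho1=0.862, rho2=0.333, rho3=0.045,
        p=0.990, pA=0.328, rP=0.461, rO=0.075,
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One default-scale synthetic dataset with its ground truth."""
    return generate(ScenarioConfig(), seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_ms_params(rng: np.random.Generator) -> MsParams:
    """A random valid parameter point, bounded away from 0/1."""
    return MsParams(*rng.uniform(0.05, 0.95, size=11))
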