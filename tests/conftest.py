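import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from gxemlp.population import direct_case_control
from gxemlp.risk_models import GenotypeDistribution, get_spec


@pytest.fixture(scope="session")
def dist():
    return GenotypeDistribution(0.30)


@pytest.fixture(scope="session")
def masking1_dataset(dist):
    """A balanced 500+500 draw from masking model 1, high risk."""
    spec = get_spec("masking_1:high")
    return direct_case_control(spec, dist, 500, 500, seed=20210)


@pytest.fixture(scope="session")
def warm_kernels(masking1_dataset):
    """Trigger numba compilation once so timings are not attributed to one test."""
    from gxemlp.mlp import MLP, TrainConfig

    ds = masking1_dataset
    X = np.column_stack([ds.genotype[:60], ds.exposure[:60]])
    MLP(ds.status[:60], X, m_hidden=1).fit(TrainConfig(stepmax=3), rng=0)
    return True
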