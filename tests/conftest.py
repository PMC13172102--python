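import pytest

from tddmri import AcquisitionScheme
from tddmri.mapping import FitConfig, ImpulsedModelCache


@pytest.fixture(scope="session")
def scheme() -> AcquisitionScheme:
    """The bundled 9-measurement OGSE/PGSE protocol."""
    return AcquisitionScheme.paper_protocol()


@pytest.fixture(scope="session")
def fit_config() -> FitConfig:
    return FitConfig()


@pytest.fixture(scope="session")
def model_cache(scheme, fit_config) -> ImpulsedModelCache:
    """Session-wide spline cache: tabulating the sphere signal over the
    diameter grid is the expensive step and is identical across tests."""
    return ImpulsedModelCache(scheme, fit_config)
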