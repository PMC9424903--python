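import numpy as np
import pytest

from spatialtme.gating import default_gating_config, derive_thresholds
from spatialtme.simulate import TissueSimParams, generate_tissue_field, sample_fmo


@pytest.fixture(scope="session")
def tissue_params():
    return TissueSimParams(seed=7)


@pytest.fixture(scope="session")
def field(tissue_params):
    """One default simulated field (cells, nests)."""
    return generate_tissue_field(tissue_params)


@pytest.fixture(scope="session")
def gating_config(tissue_params):
    """High-fidelity gating config: FMO thresholds at the 0.999 quantile."""
    fmo = sample_fmo(tissue_params, n=20000, rng=np.random.default_rng(123))
    return default_gating_config(derive_thresholds(fmo, 0.999), positivity_quantile=0.999)
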