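import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from proxnet.network import ContactNetwork

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_network(adjacency, covariates=None, names=(), dyad_mask=None):
    """ContactNetwork from an adjacency matrix and optional covariate matrix."""
    adjacency = np.asarray(adjacency, dtype=bool)
    n = adjacency.shape[0]
    actors = [f"a{i:03d}" for i in range(n)]
    if covariates is None:
        cov = pd.DataFrame(index=pd.Index(actors))
    else:
        cov = pd.DataFrame(np.asarray(covariates, dtype=float).reshape(n, -1),
                           index=pd.Index(actors), columns=list(names))
    return ContactNetwork(actors=actors, adjacency=adjacency, covariates=cov,
                          dyad_mask=dyad_mask)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
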