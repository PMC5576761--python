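import numpy as np
import pytest

from screenrep.models import Density, Domain, Scale, StudyMatrix, TwoGroupsModel


def make_model(pi0=0.9, mu=3.0, sigma1=1.0, domain=Domain.signed_z):
    """Hand-built two-groups model with a standard normal null."""
    return TwoGroupsModel(
        pi0=pi0,
        null=Density("normal", (0.0, 1.0)),
        nonnull=Density("normal", (mu, sigma1)),
        domain=domain,
    )


def random_models(m, rng):
    return [
        make_model(pi0=rng.uniform(0.6, 0.95), mu=rng.uniform(1.5, 4.0))
        for _ in range(m)
    ]


def random_matrix(n, m, rng, scale=Scale.zscore):
    vals = rng.standard_normal((n, m))
    if scale is Scale.pvalue:
        vals = rng.random((n, m))
    return StudyMatrix(
        vals,
        [f"g{i}" for i in range(n)],
        [f"s{j}" for j in range(m)],
        scale,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
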