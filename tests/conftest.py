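import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_problem():
    """A 6-species dataset with its covariance set, for quick sampler runs."""
    from phylosurv.simulate import GenParams, generate_dataset
    from phylosurv.trees import CovarianceSet, random_tree, scale_vcv, tree_vcv

    gp = GenParams(n_species=6)
    tree = random_tree(6, seed=42)
    V, labels = tree_vcv(tree)
    C = scale_vcv(V)
    ds = generate_dataset(gp, C, seed=99, species=labels)
    return ds, CovarianceSet([C], labels)
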