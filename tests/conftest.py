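import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from exciham import synthetic

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ref_geom():
    return synthetic.reference_geometry()


@pytest.fixture(scope="session")
def small_ensemble():
    return synthetic.generate_chromophore_ensemble(40, seed=7)


@pytest.fixture(scope="session")
def small_envs():
    return [
        synthetic.generate_environment(n_residues=12, seed=7, sample_index=i)
        for i in range(40)
    ]


@pytest.fixture(scope="session")
def small_bundle():
    """Modest train/test bundle shared across model tests."""
    return synthetic.make_bundle(n_train=120, n_test=40, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
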