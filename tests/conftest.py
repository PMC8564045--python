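import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import parenclitic as pc

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_sphere():
    """10-dim ideal sphere, 20/20 TRAIN and 5/5 TEST, fixed seed."""
    spec = pc.SphereSpec(model_kind="ideal", dim=10,
                         n_case_train=20, n_control_train=20,
                         n_case_test=5, n_control_test=5, seed=7)
    return pc.sample_ideal_sphere(spec)


@pytest.fixture(scope="session")
def tiny_sphere():
    """4-dim ideal sphere kept small so wSA fits stay cheap."""
    spec = pc.SphereSpec(model_kind="ideal", dim=4,
                         n_case_train=15, n_control_train=15,
                         n_case_test=4, n_control_test=4, seed=3)
    return pc.sample_ideal_sphere(spec)


@pytest.fixture(scope="session")
def tiny_models_wsa(tiny_sphere):
    return pc.fit_pair_models(tiny_sphere.table.train(), "wSA", seed=0)
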