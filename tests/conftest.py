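import numpy as np
import pytest
from hypothesis import settings

from nestipm import inference as inf
from nestipm import simulate as sim

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_truth():
    """A short study kept small so fits stay fast in the suite."""
    return sim.TruthSet(n_years=12, n_boxes=60, init_NY=25, init_NA=50)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    return sim.simulate_dataset(small_truth, seed=421)


@pytest.fixture(scope="session")
def small_bundle(small_dataset, tmp_path_factory):
    d = tmp_path_factory.mktemp("ds")
    small_dataset.write(d)
    return inf.load_dataset_dir(d)


@pytest.fixture(scope="session")
def tiny_fit(small_bundle):
    """A short two-chain fit shared by tests that need posterior draws."""
    cfg = inf.FitConfig(n_chains=2, n_iter=2000, n_burnin=800, thin=4,
                        seed=17)
    return inf.fit_ipm(small_bundle, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
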