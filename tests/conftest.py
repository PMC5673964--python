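import numpy as np
import pytest

import venomminer as vm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def registry():
    return vm.load_registry()


@pytest.fixture(scope="session")
def small_scenario():
    """A small but complete synthetic study shared by pipeline-level tests."""
    return vm.make_scenario(7, n_planted=5, n_decoys=30, n_unvalidatable=1)


@pytest.fixture(scope="session")
def small_method3(small_scenario):
    sc = small_scenario
    cfg = vm.RunConfig(e_max=sc.e_max, seed=sc.seed)
    return vm.run_method3(sc.reads, sc.group_sets, cfg, sc.registry)


def random_protein(rng, n, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))
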