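import numpy as np
import pytest

from metaplots import synth


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """A cheap synthetic dataset shared by format/collection/plot tests."""
    return synth.make_scenario(
        tmp_path_factory.mktemp("small"),
        seed=5,
        n_per_class=4,
        n_classes=3,
        upstream=200,
        downstream=300,
        noise_sd=0.3,
    )


@pytest.fixture(scope="session")
def e2e_scenario(tmp_path_factory):
    """The full-size synthetic dataset (5 classes, 3 tracks + genome)."""
    return synth.make_scenario(tmp_path_factory.mktemp("e2e"), seed=11)


@pytest.fixture(scope="session")
def e2e_noisefree(tmp_path_factory):
    """Noise-free variant: profiles and clusters are analytically exact."""
    return synth.make_scenario(
        tmp_path_factory.mktemp("e2e0"), seed=11, noise_sd=0.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
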