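import numpy as np
import pytest

from didomain.synthetic import ScenarioSpec, interface_residues, make_toy_didomain


@pytest.fixture(scope="session")
def toy():
    """Contacting toy di-domain: (model, domain_a, domain_b)."""
    return make_toy_didomain()


@pytest.fixture(scope="session")
def toy_detached():
    return make_toy_didomain(detached=True)


@pytest.fixture(scope="session")
def toy_interface(toy):
    model, dom_a, dom_b = toy
    return interface_residues(model, dom_a, dom_b)


@pytest.fixture
def dynamic_spec():
    return ScenarioSpec.preset("dynamic", seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1)[:, None]
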