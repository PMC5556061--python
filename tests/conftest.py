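import numpy as np
import pytest

from sh3kit.motif import MotifPattern
from sh3kit.structure import Selection
from sh3kit.synth import gen_complex_ensemble, template_complex


@pytest.fixture(scope="session")
def pattern():
    return MotifPattern.default()


@pytest.fixture(scope="session")
def template():
    return template_complex()


@pytest.fixture(scope="session")
def ligand_selection():
    return Selection(chain="B")


@pytest.fixture(scope="session")
def small_ensemble():
    stack, truth = gen_complex_ensemble(n_models=10, jitter_sd=0.15, seed=11)
    return stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
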