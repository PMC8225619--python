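import numpy as np
import pytest

from foldstrain.blueprint import parse_blueprint
from foldstrain.fragments import make_synthetic_fragments
from foldstrain.sampler import MCConfig, generate_ensemble

TOY_HAIRPIN = "name toy_hairpin\nE 4\nL GG\nE 4\nP 1 3 3 anti\n"
TOY_PARALLEL = "name toy_parallel\nE 5\nL BBB\nH 12\nL BBB\nE 5\nP 1 5 0 par\n"


@pytest.fixture(scope="session")
def hairpin_bp():
    return parse_blueprint(TOY_HAIRPIN)


@pytest.fixture(scope="session")
def parallel_bp():
    return parse_blueprint(TOY_PARALLEL)


@pytest.fixture(scope="session")
def hairpin_lib(hairpin_bp):
    return make_synthetic_fragments(hairpin_bp, 11)


@pytest.fixture(scope="session")
def hairpin_ensemble(hairpin_bp):
    ens = generate_ensemble(hairpin_bp, 8, seed=3,
                            cfg=MCConfig.desk_scale())
    assert len(ens) == 8
    return ens


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
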