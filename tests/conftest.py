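import numpy as np
import pytest

from gmshift.chem_graph import build_rooted_dag, parse_tagged_smiles
from gmshift.node_model import NodeFunctionParameters, ScalingSpec
from gmshift.synthetic import make_dataset


@pytest.fixture(scope="session")
def shift_scaling():
    return ScalingSpec.from_range(73.0, 166.0)


@pytest.fixture(scope="session")
def benzene_dag():
    return build_rooted_dag(parse_tagged_smiles("[cH:1]1ccccc1"))


@pytest.fixture(scope="session")
def methoxytoluene_dag():
    return build_rooted_dag(parse_tagged_smiles("COc1[c:1](C)cccc1"))


@pytest.fixture(scope="session")
def small_additive_dataset():
    """Noiseless additive-increment data: 30 molecules, deterministic."""
    return make_dataset(30, 0.0, seed=11, mode="additive")


@pytest.fixture
def random_params():
    def factory(h, seed=0, n_in=None):
        rng = np.random.default_rng(seed)
        kwargs = {} if n_in is None else {"n_in": n_in}
        return NodeFunctionParameters.random(h, rng, **kwargs)

    return factory
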