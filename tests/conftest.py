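import numpy as np
import pytest

from molcraft.synthetic import SyntheticSpec, gen_interactome, gen_pocket


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_interactome_records():
    return gen_interactome(SyntheticSpec(n_targets=4, ligands_per_target=6, seed=7))


@pytest.fixture(scope="session")
def toy_pocket():
    return gen_pocket(seed=11)


@pytest.fixture(scope="session")
def tiny_corpus():
    return ["CCO", "CCN", "c1ccccc1O", "CC(=O)O", "CCCl", "c1ccncc1", "CC(C)CO"]
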