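import numpy as np
import pytest

from petmine.align import blosum62_scheme
from petmine.hmm import build_profile
from petmine.msa import progressive_align
from petmine.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def scheme():
    return blosum62_scheme()


@pytest.fixture(scope="session")
def tiny_world():
    """A small synthetic world: 60 background proteins, 4 planted homologs."""
    spec = SyntheticSpec(
        n_background=60,
        n_seed_family=6,
        seed_length=120,
        planted=[(4, 0.5)],
        random_seed=3,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_profile(tiny_world):
    msa = progressive_align(tiny_world.seed_family)
    return build_profile(msa, name="tiny_seed_family")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
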