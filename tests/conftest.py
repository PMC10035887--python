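import numpy as np
import pytest

from ligevo.phylo import PrimatePhylogeny, load_reference_tree
from ligevo.substitution import jtt
from ligevo.synthetic import SimulationConfig, generate_binding_profiles, generate_dataset


@pytest.fixture(scope="session")
def reference_tree():
    return load_reference_tree()


@pytest.fixture(scope="session")
def jtt_model():
    return jtt()


@pytest.fixture(scope="session")
def four_leaf_tree():
    return PrimatePhylogeny.from_newick("((A:0.12,B:0.27):0.05,(C:0.33,D:0.08):0.19);")


@pytest.fixture(scope="session")
def profiles():
    return generate_binding_profiles(20, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """Small end-to-end dataset with planted human-specific sites."""
    cfg = SimulationConfig(
        n_orthogroups=4,
        seq_length_range=(120, 180),
        n_planted_human_specific=1,
        seed=7,
    )
    return generate_dataset(cfg, n_domains=25)
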