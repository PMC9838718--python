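import numpy as np
import pytest

from ecnbs.core import ConnectomeStack, Phenotype
from ecnbs.synthetic import SyntheticDesign, blocked_edge_partition, generate_stack


@pytest.fixture(scope="session")
def ten_community_partition():
    """Planted 10-community partition over the 190 edges of 20 nodes."""
    return blocked_edge_partition(20, 10)


@pytest.fixture(scope="session")
def null_design(ten_community_partition):
    """Fully null binary design: no planted effects anywhere."""
    return SyntheticDesign(
        n_nodes=20,
        n_subjects=200,
        true_partition=ten_community_partition,
        phenotype_kind="binary",
        target_effects={},
        community_coupling=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def null_data(null_design):
    return generate_stack(null_design)


@pytest.fixture(scope="session")
def planted_design(ten_community_partition):
    """One strong positive community (d = 0.8 in community 3)."""
    return SyntheticDesign(
        n_nodes=20,
        n_subjects=400,
        true_partition=ten_community_partition,
        phenotype_kind="binary",
        target_effects={3: 0.8},
        community_coupling=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def planted_data(planted_design):
    return generate_stack(planted_design)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_stack():
    """Deterministic 6-subject, 3-node stack for hand calculations."""
    values = np.array(
        [
            [1.0, 0.3, -0.2],
            [2.0, 0.1, 0.4],
            [3.0, 0.5, 0.0],
            [0.0, 0.2, 0.1],
            [1.0, 0.4, -0.1],
            [2.0, 0.0, 0.3],
        ]
    )
    return ConnectomeStack(values, 3)


@pytest.fixture
def tiny_binary_phenotype():
    """Classes: first three subjects are class 1, last three class 0."""
    return Phenotype(np.array([1, 1, 1, 0, 0, 0]), "binary")
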