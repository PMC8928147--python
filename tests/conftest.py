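import numpy as np
import pandas as pd
import pytest

from divpower.community import CountTable, read_tree
from divpower.simulate import CommunitySpec, generate_base


@pytest.fixture(scope="session")
def three_leaf_tree():
    """((A:1,B:2):0.5,C:3):0; — total branch length 6.5."""
    return read_tree("((A:1,B:2):0.5,C:3):0;")


@pytest.fixture()
def tiny_table():
    return CountTable(
        pd.DataFrame(
            [[2.0, 0.0, 6.0], [1.0, 3.0, 4.0]],
            index=["s1", "s2"],
            columns=["A", "B", "C"],
        )
    )


@pytest.fixture(scope="session")
def base_community():
    """Medium synthetic pool + tree shared by the slower tests."""
    return generate_base(CommunitySpec(n_samples=60, n_features=150, seed=11))


def random_table(rng, n_samples, n_features, density=0.6, max_count=50):
    """Random sparse integer count table with no all-zero sample."""
    X = rng.integers(1, max_count, size=(n_samples, n_features))
    X = X * (rng.random((n_samples, n_features)) < density)
    for i in range(n_samples):  # keep every sample nonempty
        if X[i].sum() == 0:
            X[i, rng.integers(n_features)] = 1
    return CountTable(
        pd.DataFrame(
            X.astype(float),
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"f{j}" for j in range(n_features)],
        )
    )
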