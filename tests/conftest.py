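import numpy as np
import pandas as pd
import pytest

from phylocomm.community import CommunityMatrix
from phylocomm.synthetic_data import simulate_tree
from phylocomm.treeio import (
    apply_equal_branch_lengths,
    parse_newick,
    patristic_distance_matrix,
    perturb_branch_lengths,
)


@pytest.fixture
def toy_tree():
    """((A:1,B:1):1,C:2); — the worked example used throughout."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_dist(toy_tree):
    return patristic_distance_matrix(toy_tree)


@pytest.fixture
def balanced4():
    return parse_newick("((A,B),(C,D));")


def random_realized_tree(n_tips, seed, jitter=0.0):
    """Random Yule tree with unit branch lengths, optionally jittered so
    path lengths are not all integers."""
    tree = simulate_tree(n_tips, seed=seed)
    if jitter > 0:
        tree = perturb_branch_lengths(tree, amplitude=jitter, seed=seed + 1)
    return tree


@pytest.fixture
def toy_community_matrix():
    counts = pd.DataFrame(
        {
            "A": [3, 0, 5],
            "B": [1, 2, 0],
            "C": [0, 4, 1],
            "D": [2, 0, 0],
        },
        index=["s1", "s2", "s3"],
    )
    meta = pd.DataFrame(
        {
            "tree_id": ["t1", "t2", "t3"],
            "tree_type": ["Fremont", "hybrid", "narrowleaf"],
            "year": [2000, 2000, 2001],
        },
        index=counts.index,
    )
    return CommunityMatrix(counts, meta)
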