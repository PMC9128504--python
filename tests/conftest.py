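import io

import numpy as np
import pandas as pd
import pytest

from phylonull.io import patristic_distances, read_newick

BALANCED_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def balanced_tree():
    """Four-tip balanced tree, every branch length 1."""
    return read_newick(io.StringIO(BALANCED_NEWICK))


@pytest.fixture
def balanced_dist(balanced_tree):
    return patristic_distances(balanced_tree)


@pytest.fixture
def toy_table():
    """Three samples x four taxa; taxon totals (5, 1, 0, 3)."""
    return pd.DataFrame(
        [[2, 1, 0, 1], [3, 0, 0, 0], [0, 0, 0, 2]],
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        columns=["tA", "tB", "tC", "tD"], dtype=float)


@pytest.fixture
def toy_metadata():
    return pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "compartment": ["root", "root", "leaf"],
        "week": [3, 3, 4],
        "nam_line": ["NAM1", "NAM2", "NAM1"],
        "bbch": [14, 14, 30],
        "block": [1, 2, 1],
    }).set_index("sample_id", drop=False)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
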