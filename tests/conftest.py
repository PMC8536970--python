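import numpy as np
import pandas as pd
import pytest

import benthos as b
from benthos.simulate import RegimeSpec, simulate_dataset


@pytest.fixture
def cherry_tree() -> b.PhyloTree:
    return b.PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_table() -> b.OtuTable:
    counts = pd.DataFrame(
        [[5, 3, 0], [2, 0, 4], [1, 1, 1]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C"],
    )
    return b.OtuTable(counts)


@pytest.fixture
def two_group_map() -> b.GroupMap:
    return b.GroupMap({"s1": "G1", "s2": "G1", "s3": "G2", "s4": "G2"})


@pytest.fixture(scope="session")
def sim_small():
    """One small selection-regime dataset shared by integration tests."""
    spec = RegimeSpec(regime="selection", n_taxa=60, depth=800, seed=11)
    table, env, gmap, tree, traits = simulate_dataset(spec)
    return {"spec": spec, "table": table, "env": env, "groups": gmap,
            "tree": tree, "traits": traits}
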