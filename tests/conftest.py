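import numpy as np
import pytest

import cycleconn as cc


@pytest.fixture(scope="session")
def default_study():
    """Default two-dataset design (60 dense + 10 weekly sessions), 30 regions."""
    study, record = cc.generate_study(
        cc.default_design(n_regions=30, seed=1), cc.default_truth(seed=1)
    )
    return study, record


@pytest.fixture(scope="session")
def dense_study(default_study):
    study, record = default_study
    mask = study.sessions["dataset_id"].str.startswith("dense").to_numpy()
    return study.subset(mask), record


def union_find_components(edges, n_nodes):
    """Independent union-find oracle: connected components of an edge list."""
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    comps = {}
    for i, j in edges:
        comps.setdefault(find(i), []).append((i, j))
    return list(comps.values())


def is_connected_edge_set(edges):
    """True when the edges form exactly one connected subgraph."""
    nodes = {v for e in edges for v in e}
    comps = union_find_components(edges, max(nodes) + 1)
    return len(comps) == 1


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
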