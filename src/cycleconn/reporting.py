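"""Node- and network-level summaries of weighted connectivity patterns.

Node strength is the sum of a region's weighted edges; aggregating edge
weights over pairs of canonical functional networks (visual,
somatomotor, attention, limbic, frontoparietal, default, ...) localizes
where in the brain's large-scale organization an outcome-related
pattern concentrates.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import edge_index, n_edges
from .nbs_predict import WeightedNetwork

__all__ = ["node_strength", "aggregate_by_network", "top_edges"]


def _as_matrix(network) -> np.ndarray:
    if isinstance(network, WeightedNetwork):
        return network.matrix
    m = np.asarray(network, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("weighted network must be a square matrix")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("weighted network must be symmetric")
    return m


def node_strength(network, regions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-region strength: the sum of each region's weighted connections.

    ``regions`` optionally supplies ``region_id`` / ``region_name`` /
    ``network_name`` columns; otherwise synthetic names are used.
    The diagonal is ignored.
    """
    m = _as_matrix(network).copy()
    np.fill_diagonal(m, 0.0)
    strength = m.sum(axis=1)
    n = m.shape[0]
    if regions is not None:
        if len(regions) != n:
            raise ValueError("region table length does not match the network")
        out = regions[["region_id", "region_name", "network_name"]].copy()
    else:
        out = pd.DataFrame(
            {"region_id": np.arange(n),
             "region_name": [f"region{k:03d}" for k in range(n)],
             "network_name": ["unknown"] * n}
        )
    out["strength"] = strength
    return out


def aggregate_by_network(
    network, regions: pd.DataFrame, normalize: bool = False
) -> pd.DataFrame:
    """Sum edge weights over pairs of canonical networks.

    ``block(a, b)`` is the sum of weights over all edges with one
    endpoint in network *a* and one in *b* (each unordered edge counted
    once); with ``normalize=True`` each block is divided by the number
    of possible such edges.  Every region must appear in ``regions``.
    """
    m = _as_matrix(network)
    n = m.shape[0]
    if len(regions) < n:
        missing = sorted(set(range(n)) - set(regions["region_id"]))
        raise ValueError(f"region {missing[0]} has no network label")
    nets = regions.set_index("region_id")["network_name"]
    unlabeled = [k for k in range(n) if k not in nets.index or pd.isna(nets.get(k))]
    if unlabeled:
        raise ValueError(f"region {unlabeled[0]} has no network label")
    labels = sorted(nets.loc[list(range(n))].unique())
    counts = {a: 0 for a in labels}
    for k in range(n):
        counts[nets.loc[k]] += 1
    block = pd.DataFrame(0.0, index=labels, columns=labels)
    iu, ju = edge_index(n)
    for i, j in zip(iu, ju):
        a, b = sorted((nets.loc[int(i)], nets.loc[int(j)]))
        block.loc[a, b] += m[i, j]
    block = block + block.T - np.diag(np.diag(block))
    if normalize:
        for a in labels:
            for b in labels:
                if a == b:
                    possible = counts[a] * (counts[a] - 1) // 2
                else:
                    possible = counts[a] * counts[b]
                if possible:
                    block.loc[a, b] /= possible
    return block


def top_edges(network, fraction: float) -> pd.DataFrame:
    """The top fraction of all possible edges, by weight, descending.

    Returns ``ceil(fraction × n(n−1)/2)`` rows with columns ``i``,
    ``j``, ``weight``; ties are broken by canonical edge index.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    m = _as_matrix(network)
    n = m.shape[0]
    iu, ju = edge_index(n)
    w = m[iu, ju]
    k = math.ceil(fraction * n_edges(n))
    idx = np.arange(w.size)
    order = np.lexsort((idx, -w))[:k]
    return pd.DataFrame(
        {"i": iu[order], "j": ju[order], "weight": w[order]}
    ).reset_index(drop=True)
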