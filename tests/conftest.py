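import warnings

import numpy as np
import pytest

from topoact.communities import SystemPartition
from topoact.graph import WeightedGraph


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Sparse-graph isolation and short-run warnings are routine in tests."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*no retained weight.*")
        warnings.filterwarnings("ignore", message=".*correlation estimates will be noisy.*")
        warnings.filterwarnings("ignore", message=".*positive edges exist.*")
        yield


def graph_from_adjacency(adj: np.ndarray) -> WeightedGraph:
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    keep = adj[iu, ju] > 0
    edges = np.column_stack([iu[keep], ju[keep]]).astype(int)
    n_possible = n * (n - 1) // 2
    return WeightedGraph(
        node_ids=[f"n{i:03d}" for i in range(n)],
        adjacency=adj,
        density=edges.shape[0] / n_possible if n_possible else 0.0,
        achieved_density=edges.shape[0] / n_possible if n_possible else 0.0,
        edges=edges,
    )


def partition_from_labels(labels, types=None) -> SystemPartition:
    labels = np.asarray(labels, dtype=object)
    names = [s for s in dict.fromkeys(labels) if s != "unassigned"]
    if types is None:
        types = {name: "association" for name in names}
    return SystemPartition(
        node_ids=[f"n{i:03d}" for i in range(labels.shape[0])],
        system=labels,
        system_types=types,
        provenance="test fixture",
    )


def naive_participation_coefficient(adj, labels, variant="standard"):
    """Brute-force double-loop PC, the independent oracle."""
    n = adj.shape[0]
    labels = np.asarray(labels, dtype=object)
    systems = [s for s in dict.fromkeys(labels) if s != "unassigned"]
    pc = np.zeros(n)
    for i in range(n):
        k_tot = 0.0
        k_sys = {s: 0.0 for s in systems}
        for j in range(n):
            if i == j or labels[j] == "unassigned":
                continue
            w = adj[i, j]
            k_tot += w
            if w:
                k_sys[labels[j]] += w
        if k_tot == 0:
            pc[i] = 0.0
            continue
        acc = 0.0
        for s in systems:
            if variant == "literal" and labels[i] == s:
                continue
            acc += (k_sys[s] / k_tot) ** 2
        pc[i] = 1.0 - acc
    return pc
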