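"""Participation coefficients and connector / non-connector classification.

The participation coefficient of node *i*,

    PC_i = 1 - sum_s (k_i(s) / k_i)^2,

measures how evenly the node's connection weight spreads over the
functional systems *s* (``k_i(s)`` is the weight from *i* to nodes of
system *s*, ``k_i`` its total weight). A node whose connections stay
inside its own system scores 0; an even split over all S systems scores
1 - 1/S. PCs are computed per edge density (2-10%), summed across
densities to absorb graph-configuration differences, and nodes are
classified within each system as connectors (PC above the system
median) or non-connectors (at or below the median).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .communities import UNASSIGNED, ConsensusAssignment, SystemPartition
from .errors import InputError, ParameterError
from .graph import DEFAULT_DENSITIES, WeightedGraph, ZMatrix, threshold_density

ROLE_CONNECTOR = "connector"
ROLE_NON_CONNECTOR = "non-connector"
ROLE_EXCLUDED = "excluded"

PC_VARIANTS = ("standard", "literal")


def participation_coefficient(
    graph: WeightedGraph, partition: SystemPartition, variant: str = "standard"
) -> np.ndarray:
    """Weighted participation coefficient per node.

    Edges to unassigned nodes contribute to neither the per-system
    weights nor the total. With ``variant="standard"`` the sum runs over
    all systems including the node's own (a fully within-system node
    scores 0). ``variant="literal"`` restricts the sum to systems the
    node does not belong to, for sensitivity analysis. Isolated nodes
    (zero total weight) score 0 with a warning.
    """
    if variant not in PC_VARIANTS:
        raise ParameterError(f"variant must be one of {PC_VARIANTS}")
    if list(graph.node_ids) != list(partition.node_ids):
        raise InputError("graph and partition must share the node set")
    labels = partition.system
    systems = partition.systems()
    W = graph.adjacency
    assigned = labels != UNASSIGNED
    # membership indicator over named systems only: drops unassigned targets
    M = np.zeros((graph.n_nodes, len(systems)))
    for k, name in enumerate(systems):
        M[labels == name, k] = 1.0
    K = W @ M  # node x system weights
    k_tot = K.sum(axis=1)
    isolated = k_tot == 0
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} node(s) have no retained weight to assigned "
            "nodes; their PC is defined as 0",
            stacklevel=2,
        )
    safe = np.where(isolated, 1.0, k_tot)
    frac2 = (K / safe[:, None]) ** 2
    if variant == "literal":
        own = np.zeros(graph.n_nodes)
        for k, name in enumerate(systems):
            own[labels == name] = frac2[labels == name, k]
        pc = 1.0 - (frac2.sum(axis=1) - own)
    else:
        pc = 1.0 - frac2.sum(axis=1)
    pc[isolated] = 0.0
    # nodes can sit outside any named system yet still have a PC; callers
    # exclude them via the partition when aggregating within systems
    del assigned
    return pc


def summed_pc(
    zmatrix: ZMatrix,
    consensus: ConsensusAssignment,
    densities: tuple = DEFAULT_DENSITIES,
    variant: str = "standard",
) -> pd.DataFrame:
    """PC per density plus the across-density sum, as a node table.

    Each density uses that density's consensus assignment, mirroring the
    density-specific graph configuration.
    """
    missing = [d for d in densities if d not in consensus.partitions]
    if missing:
        raise InputError(f"consensus does not cover densities {missing}")
    out = pd.DataFrame(index=pd.Index(zmatrix.node_ids, name="node_id"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sparse graphs routinely isolate nodes
        for d in densities:
            graph = threshold_density(zmatrix, d)
            pc = participation_coefficient(
                graph, consensus.partition_at(d), variant=variant
            )
            out[f"pc_d{round(100 * d)}"] = pc
    out["pc_sum"] = out.sum(axis=1)
    return out


def classify_connectors(
    pc_sum: np.ndarray, partition: SystemPartition
) -> np.ndarray:
    """Median-split roles within each system.

    A node is a connector iff its summed PC exceeds the median summed PC
    of its own system, a non-connector otherwise (ties at the median go
    to non-connector); unassigned nodes are excluded.
    """
    pc_sum = np.asarray(pc_sum, dtype=float)
    if pc_sum.shape[0] != partition.n_nodes:
        raise InputError("pc_sum length must match the partition node count")
    roles = np.full(partition.n_nodes, ROLE_EXCLUDED, dtype=object)
    for name in partition.systems():
        members = partition.system == name
        if members.sum() < 2:
            raise ParameterError(
                f"system {name!r} has fewer than 2 nodes; median split undefined"
            )
        med = np.median(pc_sum[members])
        roles[members] = np.where(
            pc_sum[members] > med, ROLE_CONNECTOR, ROLE_NON_CONNECTOR
        )
    return roles


def node_topology_table(
    zmatrix: ZMatrix,
    consensus: ConsensusAssignment,
    densities: tuple = DEFAULT_DENSITIES,
    variant: str = "standard",
    classify_at: float | None = None,
) -> pd.DataFrame:
    """Full per-node topology table: per-density PCs, summed PC, system, role.

    Classification uses the summed PC by default; pass ``classify_at``
    to classify on a single density's PC instead. The system / role
    columns come from the consensus at the lowest requested density's
    partition unless ``classify_at`` selects another one.
    """
    table = summed_pc(zmatrix, consensus, densities, variant=variant)
    if classify_at is not None:
        ref_density = classify_at
    else:
        # systems are near-identical across densities; use the density that
        # assigns the most nodes (ties -> lowest density) for the role split
        assigned = [
            (int(consensus.partition_at(d).assigned_mask().sum()), -d) for d in densities
        ]
        ref_density = densities[int(np.argmax([a[0] + 1e-9 * a[1] for a in assigned]))]
    partition = consensus.partition_at(ref_density)
    score = (
        table[f"pc_d{round(100 * ref_density)}"].to_numpy()
        if classify_at is not None
        else table["pc_sum"].to_numpy()
    )
    table["system"] = partition.system
    table["system_type"] = partition.type_of_node()
    table["role"] = classify_connectors(score, partition)
    return table
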