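"""Community detection, reference labeling, and bootstrap consensus.

Communities are detected on density-thresholded weighted graphs with a
map-equation-minimizing algorithm (Infomap, via the igraph backend),
matched to a named reference partition by optimal one-to-one overlap
assignment, and made reliable per age group by bootstrap: resample
participants with replacement, average their z-matrices, threshold at
each density, detect, label — and keep, per node per density, the modal
label across bootstraps.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
from scipy.optimize import linear_sum_assignment

from ._seeds import child_seed_ints, substream
from .errors import InputError, ParameterError
from .graph import DEFAULT_DENSITIES, WeightedGraph, mean_zmatrix, threshold_density

UNASSIGNED = "unassigned"

#: Systems smaller than this node count are left unlabeled, echoing the
#: exclusion of systems with too few nodes; configurable everywhere.
MIN_NODES = 5


@dataclass
class Partition:
    """A detected community partition: contiguous integer labels from 0."""

    membership: np.ndarray
    quality: float
    seed: int

    def __post_init__(self):
        m = np.asarray(self.membership, dtype=int)
        labels = np.unique(m)
        if labels.size and (labels[0] != 0 or labels[-1] != labels.size - 1):
            # remap to contiguous 0..k-1 preserving first-appearance order
            order = {}
            for lab in m:
                order.setdefault(int(lab), len(order))
            m = np.array([order[int(lab)] for lab in m])
        self.membership = m

    @property
    def n_communities(self) -> int:
        return int(self.membership.max()) + 1 if self.membership.size else 0

    def community_sizes(self) -> np.ndarray:
        return np.bincount(self.membership, minlength=self.n_communities)


@dataclass
class SystemPartition:
    """Node-to-system labels with system-type annotation.

    ``system_types`` maps each system name to sensory-motor /
    association / default; unassigned nodes carry no system type and are
    excluded from within-system statistics.
    """

    node_ids: list
    system: np.ndarray  # per-node system name, UNASSIGNED allowed
    system_types: dict
    provenance: str = ""

    def __post_init__(self):
        self.system = np.asarray(self.system, dtype=object)
        if len(self.node_ids) != self.system.shape[0]:
            raise InputError("node_ids and system labels differ in length")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def assigned_mask(self) -> np.ndarray:
        return self.system != UNASSIGNED

    def type_of_node(self) -> np.ndarray:
        """Per-node system type; UNASSIGNED for unassigned nodes."""
        return np.array(
            [
                self.system_types.get(s, UNASSIGNED) if s != UNASSIGNED else UNASSIGNED
                for s in self.system
            ],
            dtype=object,
        )

    def systems(self) -> list:
        out = []
        for s in self.system:
            if s != UNASSIGNED and s not in out:
                out.append(s)
        return out


@dataclass
class ConsensusAssignment:
    """Per-density modal system labels with bootstrap agreement."""

    densities: tuple
    partitions: dict  # density -> SystemPartition
    agreement: dict  # density -> per-node modal proportion across bootstraps
    n_boot: int
    ties: list = field(default_factory=list)  # (density, node_id, tied labels)

    def partition_at(self, density: float) -> SystemPartition:
        try:
            return self.partitions[density]
        except KeyError:
            raise InputError(
                f"no consensus at density {density}; have {sorted(self.partitions)}"
            ) from None


# ----------------------------------------------------------------------


def detect_communities(
    graph: WeightedGraph, seed: int, trials: int = 5, backend: str = "infomap"
) -> Partition:
    """Detect communities on a thresholded weighted graph.

    The backend contract: deterministic given ``seed``; isolated nodes
    become singleton communities. The default backend minimizes the map
    equation (Infomap).
    """
    if graph.n_nodes == 0:
        raise InputError("cannot detect communities on an empty graph")
    if backend != "infomap":
        raise ParameterError(f"unknown community backend {backend!r}")
    g = ig.Graph(graph.n_nodes, [tuple(e) for e in graph.edges])
    weights = graph.adjacency[graph.edges[:, 0], graph.edges[:, 1]] if graph.n_edges else []
    ig.set_random_number_generator(random.Random(int(seed)))
    try:
        clustering = g.community_infomap(
            edge_weights=list(weights) if graph.n_edges else None, trials=trials
        )
    finally:
        ig.set_random_number_generator(random)
    quality = getattr(clustering, "codelength", float("nan"))
    return Partition(
        membership=np.asarray(clustering.membership, dtype=int),
        quality=float(quality),
        seed=int(seed),
    )


def match_labels(
    partition: Partition, reference: SystemPartition, min_nodes: int = MIN_NODES
) -> SystemPartition:
    """Name detected communities by overlap with the reference systems.

    Solves an optimal one-to-one assignment on the community-by-system
    overlap-count matrix. Communities smaller than ``min_nodes`` or with
    zero overlap with every reference system are labeled unassigned.
    The result is invariant to any relabeling of the detected partition.
    """
    membership = partition.membership
    if membership.shape[0] != reference.n_nodes:
        raise InputError("partition and reference must share the node set")
    ref_systems = reference.systems()
    n_comm = partition.n_communities
    overlap = np.zeros((n_comm, len(ref_systems)), dtype=int)
    for k, name in enumerate(ref_systems):
        counts = np.bincount(membership[reference.system == name], minlength=n_comm)
        overlap[:, k] = counts
    rows, cols = linear_sum_assignment(-overlap)
    sizes = partition.community_sizes()
    comm_name = np.full(n_comm, UNASSIGNED, dtype=object)
    for c, k in zip(rows, cols):
        if overlap[c, k] > 0 and sizes[c] >= min_nodes:
            comm_name[c] = ref_systems[k]
    return SystemPartition(
        node_ids=list(reference.node_ids),
        system=comm_name[membership],
        system_types=dict(reference.system_types),
        provenance=f"matched to reference ({reference.provenance})",
    )


def modal_label(counts: dict) -> tuple:
    """Most frequent label with a deterministic tie rule.

    Returns ``(label, tied, count)``: frequency ties are broken toward
    the lexicographically smallest label name, and ``tied`` lists every
    tied label (empty when the mode is unique).
    """
    if not counts:
        raise InputError("no label counts")
    best = max(counts.values())
    winners = sorted(name for name, c in counts.items() if c == best)
    return winners[0], winners if len(winners) > 1 else [], best


def consensus_assignment(
    zmatrices: list,
    reference: SystemPartition,
    densities: tuple = DEFAULT_DENSITIES,
    n_boot: int = 1000,
    seed: int = 0,
    min_nodes: int = MIN_NODES,
    trials: int = 5,
) -> ConsensusAssignment:
    """Bootstrap-consensus system labels per edge density.

    For each bootstrap: resample participants with replacement, average
    their z-matrices, threshold at each density, detect communities and
    match them to the reference. Per node per density the modal label
    across bootstraps is kept, with its frequency as the agreement
    proportion. Frequency ties are broken toward the lexicographically
    smallest label and recorded.
    """
    if len(zmatrices) < 2:
        raise InputError("need at least 2 participants to bootstrap")
    if n_boot < 1:
        raise InputError("n_boot must be >= 1")
    ss = substream(seed, "consensus")
    resample_rng = np.random.default_rng(ss.spawn(1)[0])
    detect_seeds = child_seed_ints(ss, n_boot * len(densities))
    n_nodes = reference.n_nodes
    label_names = [UNASSIGNED] + list(reference.systems())
    label_index = {name: k for k, name in enumerate(label_names)}
    counts = {d: np.zeros((n_nodes, len(label_names)), dtype=int) for d in densities}

    for b in range(n_boot):
        idx = resample_rng.integers(0, len(zmatrices), size=len(zmatrices))
        boot_mean = mean_zmatrix([zmatrices[i] for i in idx])
        for j, d in enumerate(densities):
            graph = threshold_density(boot_mean, d)
            part = detect_communities(
                graph, seed=detect_seeds[b * len(densities) + j], trials=trials
            )
            labeled = match_labels(part, reference, min_nodes=min_nodes)
            for i, name in enumerate(labeled.system):
                counts[d][i, label_index[name]] += 1

    partitions, agreement, ties = {}, {}, []
    for d in densities:
        labels = np.empty(n_nodes, dtype=object)
        agree = np.empty(n_nodes)
        for i in range(n_nodes):
            label, tied, best = modal_label(dict(zip(label_names, counts[d][i])))
            labels[i] = label
            agree[i] = best / n_boot
            if tied:
                ties.append((d, reference.node_ids[i], tied))
        partitions[d] = SystemPartition(
            node_ids=list(reference.node_ids),
            system=labels,
            system_types=dict(reference.system_types),
            provenance=f"bootstrap consensus (n_boot={n_boot}, density={d})",
        )
        agreement[d] = agree
    return ConsensusAssignment(
        densities=tuple(densities),
        partitions=partitions,
        agreement=agreement,
        n_boot=n_boot,
        ties=ties,
    )
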