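"""Fisher-z correlation matrices and density-thresholded weighted graphs."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateCorrelationError, InputError, ZeroVarianceError
from .preprocess import CleanTimeSeries

#: Edge densities used throughout the analyses: 2-10% in 1% steps.
DEFAULT_DENSITIES = tuple(np.round(np.arange(0.02, 0.101, 0.01), 2))


@dataclass
class ZMatrix:
    """Symmetric node-by-node Fisher-z correlation matrix.

    The diagonal is stored as 0 and excluded from all edge computations.
    With ``negatives_removed`` every off-diagonal entry is >= 0.
    """

    node_ids: list
    z: np.ndarray
    negatives_removed: bool = True

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise InputError(f"z must be square, got {z.shape}")
        if len(self.node_ids) != z.shape[0]:
            raise InputError("node_ids length must match matrix size")
        if np.abs(z - z.T).max(initial=0.0) > 1e-12:
            raise InputError("z matrix must be symmetric within 1e-12")
        self.z = (z + z.T) / 2.0
        np.fill_diagonal(self.z, 0.0)
        if self.negatives_removed and (self.z < 0).any():
            raise InputError("negatives_removed is set but negative entries remain")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]

    def strength(self) -> np.ndarray:
        """Node strength k_i^w on the complete (density-1) positive graph."""
        return self.z.sum(axis=1)


@dataclass
class WeightedGraph:
    """Undirected weighted graph retaining the strongest edges.

    ``adjacency`` is symmetric with zeros for discarded edges;
    ``density`` is the requested proportion of possible edges and
    ``achieved_density`` what was actually retained (fewer positive
    edges than requested leads to a shortfall).
    """

    node_ids: list
    adjacency: np.ndarray
    density: float
    achieved_density: float
    edges: np.ndarray = field(repr=False)  # m x 2 int array, i < j

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def strength(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


def correlation_zmatrix(
    ts, node_ids: list | None = None, drop_negatives: bool = True
) -> ZMatrix:
    """Pearson correlations of all node pairs, Fisher-transformed.

    ``z = atanh(r)``; with ``drop_negatives`` (the default) negative
    edges are set to zero before any downstream use.
    """
    if isinstance(ts, CleanTimeSeries):
        ts = ts.data
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise InputError(f"time series must be frames x nodes, got {ts.shape}")
    n_frames, n_nodes = ts.shape
    if n_frames < 3:
        raise InputError(f"need at least 3 frames, got {n_frames}")
    if node_ids is None:
        node_ids = [f"n{i:03d}" for i in range(n_nodes)]
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ZeroVarianceError(
            f"node {node_ids[dead[0]]} has zero variance; correlation undefined"
        )
    r = np.corrcoef(ts, rowvar=False)
    off = ~np.eye(n_nodes, dtype=bool)
    sat = np.abs(r[off]) >= 1.0 - 1e-15
    if sat.any():
        i, j = np.argwhere((np.abs(r) >= 1.0 - 1e-15) & off)[0]
        raise DegenerateCorrelationError(
            f"|r| = 1 between nodes {node_ids[i]} and {node_ids[j]}: "
            "Fisher's z diverges"
        )
    np.fill_diagonal(r, 0.0)  # diagonal excluded; avoids atanh(1) overflow
    z = np.arctanh(r)
    if drop_negatives:
        z = np.where(z < 0.0, 0.0, z)
    return ZMatrix(node_ids=list(node_ids), z=z, negatives_removed=drop_negatives)


def _edge_order(z: np.ndarray):
    """Upper-triangle edges sorted by descending weight, ties by (i, j)."""
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = z[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order], w[order]


def threshold_density(zmatrix: ZMatrix, density: float) -> WeightedGraph:
    """Retain the top ``round(density * N(N-1)/2)`` weighted edges.

    Edge-count rounding is round-half-up; ties at the cutoff weight are
    broken by lexicographic (i, j) order for cross-platform
    reproducibility. The graph stays weighted.
    """
    if not 0.0 < density <= 1.0:
        raise InputError(f"density must lie in (0, 1], got {density}")
    if not zmatrix.negatives_removed:
        raise InputError("negative edges must be removed before thresholding")
    n = zmatrix.n_nodes
    n_possible = n * (n - 1) // 2
    m = int(np.floor(density * n_possible + 0.5))
    iu, ju, w = _edge_order(zmatrix.z)
    positive = int((w > 0).sum())
    if positive < m:
        warnings.warn(
            f"requested {m} edges at density {density:.3f} but only "
            f"{positive} positive edges exist; retaining all of them",
            stacklevel=2,
        )
        m = positive
    iu, ju, w = iu[:m], ju[:m], w[:m]
    adj = np.zeros((n, n))
    adj[iu, ju] = w
    adj[ju, iu] = w
    return WeightedGraph(
        node_ids=list(zmatrix.node_ids),
        adjacency=adj,
        density=float(density),
        achieved_density=m / n_possible if n_possible else 0.0,
        edges=np.column_stack([iu, ju]).astype(int),
    )


def mean_zmatrix(zmatrices: list, weights=None) -> ZMatrix:
    """Participant-average z-matrix (mean of z, not of r)."""
    if not zmatrices:
        raise InputError("need at least one z-matrix to average")
    node_ids = zmatrices[0].node_ids
    neg_removed = all(z.negatives_removed for z in zmatrices)
    stack = np.stack([z.z for z in zmatrices])
    mean = np.average(stack, axis=0, weights=weights)
    return ZMatrix(node_ids=list(node_ids), z=mean, negatives_removed=neg_removed)
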