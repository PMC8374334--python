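"""Module-aware edge vectorization and the grouped design matrix.

Each subject's connectivity matrix is rearranged so nodes of one module are
adjacent, then the strict upper triangle is unrolled into an edge vector of
length d = m(m-1)/2.  The vector is ordered: all *within-module* edges first
(module 0's block, then module 1's, ...; row-major inside each block), then
all *between-module* edges (module pairs in lexicographic order, row-major
inside each pair block).  Features are grouped for the group LASSO: the
within-module edges of module k form one group; every between-module edge is
its own singleton group, giving G = K' + d_b groups where K' counts modules
with at least two nodes (singleton modules contribute no within edges and
their group slot is dropped).

``edge_map`` records, for every feature index, the unordered pair of
*original* node indices it came from, so selected features map back to region
pairs regardless of the rearrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fbn import ConnectivityMatrix
from .modules import ModulePartition, _as_matrix

__all__ = [
    "GroupedDesign",
    "rearrange_adjacency",
    "vectorize_grouped",
    "build_design",
    "vectorize_edges",
    "edge_pairs",
]


def edge_pairs(m: int) -> list[tuple[int, int]]:
    """Unordered node pairs in plain upper-triangle (row-major) order."""
    iu = np.triu_indices(m, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def vectorize_edges(W) -> np.ndarray:
    """Plain upper-triangle edge vector (no module ordering)."""
    A = _as_matrix(W)
    return A[np.triu_indices(A.shape[0], k=1)]


@dataclass
class GroupedDesign:
    """N x d edge-feature matrix with its group structure.

    group_index[j] is the group id (0..G-1) of feature j; groups 0..K'-1 are
    the within-module groups, the rest are between-module singletons.
    """

    X: np.ndarray
    group_index: np.ndarray
    group_sizes: np.ndarray
    edge_map: list[tuple[int, int]]
    K: int
    d_w: int
    d_b: int
    region_ids: list[str] | None = None
    n_within_groups: int = field(init=False)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.group_index = np.asarray(self.group_index, dtype=int)
        self.group_sizes = np.asarray(self.group_sizes, dtype=int)
        d = self.X.shape[1]
        if len(self.group_index) != d or len(self.edge_map) != d:
            raise ValueError("group_index/edge_map length must match feature count")
        if self.group_sizes.sum() != d:
            raise ValueError("group sizes must sum to the feature count")
        # within groups come first; the trailing d_b groups are the singletons
        self.n_within_groups = len(self.group_sizes) - self.d_b

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def edge_regions(self, j: int) -> tuple[str, str]:
        i, k = self.edge_map[j]
        if self.region_ids is None:
            return (str(i), str(k))
        return (self.region_ids[i], self.region_ids[k])


def rearrange_adjacency(W, P: ModulePartition):
    """Symmetrically permute W so nodes of one module are adjacent.

    Returns the same type as the input (ConnectivityMatrix in, matrix out
    with permuted region labels; ndarray in, ndarray out).
    """
    A = _as_matrix(W)
    if P.n_nodes != A.shape[0]:
        raise ValueError("partition does not match network size")
    order = P.order
    B = A[np.ix_(order, order)]
    if isinstance(W, ConnectivityMatrix):
        ids = [W.region_ids[i] for i in order]
        return ConnectivityMatrix(B, ids, W.estimator_tag)
    return B


def _grouping_metadata(P: ModulePartition):
    """Feature order, edge map and group structure induced by a partition."""
    edge_order: list[tuple[int, int]] = []
    group_index: list[int] = []
    group_sizes: list[int] = []
    gid = 0
    for k in range(P.K):
        members = P.members(k)
        nk = len(members)
        if nk < 2:
            continue  # singleton module: no within edges, group slot dropped
        for a in range(nk):
            for b in range(a + 1, nk):
                i, j = int(members[a]), int(members[b])
                edge_order.append((min(i, j), max(i, j)))
                group_index.append(gid)
        group_sizes.append(nk * (nk - 1) // 2)
        gid += 1
    d_w = len(edge_order)
    for k in range(P.K):
        for l in range(k + 1, P.K):
            for i in P.members(k):
                for j in P.members(l):
                    edge_order.append((int(min(i, j)), int(max(i, j))))
                    group_index.append(gid)
                    group_sizes.append(1)
                    gid += 1
    d_b = len(edge_order) - d_w
    return edge_order, np.array(group_index), np.array(group_sizes), d_w, d_b


def vectorize_grouped(W, P: ModulePartition):
    """Edge vector of W in module-grouped order, with its group metadata.

    Returns ``(vector, design)`` where ``design`` is a single-row
    GroupedDesign carrying the shared metadata (edge_map, groups).
    """
    A = _as_matrix(W)
    edge_order, group_index, group_sizes, d_w, d_b = _grouping_metadata(P)
    vec = np.array([A[i, j] for i, j in edge_order])
    ids = W.region_ids if isinstance(W, ConnectivityMatrix) else None
    design = GroupedDesign(
        vec[None, :], group_index, group_sizes, edge_order, P.K, d_w, d_b, ids
    )
    return vec, design


def build_design(Ws, P: ModulePartition) -> GroupedDesign:
    """Stack the grouped edge vectors of several subjects into one design.

    Row i of X is the grouped edge vector of network i; all rows share the
    group metadata induced by the partition P.
    """
    mats = [_as_matrix(W) for W in Ws]
    if not mats:
        raise ValueError("need at least one network")
    m = P.n_nodes
    if any(M.shape[0] != m for M in mats):
        raise ValueError("networks have mismatched node sets")
    edge_order, group_index, group_sizes, d_w, d_b = _grouping_metadata(P)
    rows = np.array(edge_order)
    X = np.stack([M[rows[:, 0], rows[:, 1]] for M in mats])
    ids = None
    for W in Ws:
        if isinstance(W, ConnectivityMatrix):
            ids = W.region_ids
            break
    return GroupedDesign(X, group_index, group_sizes, edge_order, P.K, d_w, d_b, ids)
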