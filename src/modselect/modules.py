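"""Module discovery in signed networks by signed spectral clustering.

Ordinary spectral clustering assumes nonnegative edge weights; a functional
brain network is signed.  The signed variant replaces the degree d_i = sum_j
w_ij with the *signed degree* d_i = sum_j |w_ij|, which keeps the normalized
Laplacian

    L = I - D^{-1/2} W D^{-1/2},   D = diag(d_1, ..., d_m)

symmetric positive semi-definite with spectrum in [0, 2] even when W has
negative entries.  Clustering proceeds exactly as in the classical algorithm:
take the eigenvectors of the K smallest eigenvalues of L, stack them
column-wise into U, normalize each row of U to unit length, and run k-means
on the rows.  The partition quality objective is the signed normalized cut

    sNcut(A_1, ..., A_K) = sum_k (x_k' L x_k) / (x_k' D x_k)

with x_k the 0/1 indicator of module k; spectral clustering minimises its
continuous relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from .fbn import ConnectivityMatrix

__all__ = [
    "SignedLaplacian",
    "ModulePartition",
    "signed_degree",
    "signed_normalized_laplacian",
    "signed_spectral_clustering",
    "sncut",
    "consensus_partition",
]


@dataclass
class SignedLaplacian:
    """Signed normalized Laplacian L with its signed degree vector."""

    L: np.ndarray
    degrees: np.ndarray

    def eigenvalues(self) -> np.ndarray:
        return scipy.linalg.eigvalsh(self.L)


@dataclass
class ModulePartition:
    """Assignment of m nodes to K modules (labels 0..K-1).

    ``order`` is a permutation of node indices that makes equal labels
    contiguous (module 0 first); it is the permutation used to rearrange
    adjacency matrices into block form.
    """

    labels: np.ndarray
    K: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if len(present) != self.K:
            raise ValueError(
                f"partition must use exactly K={self.K} labels, found {len(present)}"
            )
        if present.min() < 0 or present.max() >= self.K:
            raise ValueError("labels must lie in 0..K-1")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def order(self) -> np.ndarray:
        return np.argsort(self.labels, kind="stable")

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K)

    def write(self, path, region_ids=None, sep="\t") -> None:
        import pandas as pd

        ids = region_ids if region_ids is not None else range(self.n_nodes)
        pd.DataFrame({"region_id": list(ids), "module": self.labels}).to_csv(
            path, sep=sep, index=False
        )


def _as_matrix(W) -> np.ndarray:
    if isinstance(W, ConnectivityMatrix):
        return W.W
    W = np.asarray(W, dtype=float)
    if np.abs(W - W.T).max() > 1e-8:
        raise ValueError("adjacency matrix must be symmetric")
    return W


def signed_degree(W) -> np.ndarray:
    """Signed degree d_i = sum_j |w_ij| of every node."""
    A = _as_matrix(W)
    return np.abs(A).sum(axis=1)


def signed_normalized_laplacian(W) -> SignedLaplacian:
    """L = I - D^{-1/2} W D^{-1/2} with D the signed degree matrix.

    Raises on isolated nodes (d_i = 0), for which the normalization is
    undefined; callers may drop or reconnect such nodes first.
    """
    A = _as_matrix(W)
    d = signed_degree(A)
    isolated = np.flatnonzero(d <= 0)
    if len(isolated):
        raise ValueError(f"isolated node(s) with zero signed degree: {isolated.tolist()}")
    inv_sqrt = 1.0 / np.sqrt(d)
    L = -A * np.outer(inv_sqrt, inv_sqrt)
    np.fill_diagonal(L, 1.0)  # diagonal of W is 0, so I - 0 = I
    L = (L + L.T) / 2.0
    return SignedLaplacian(L, d)


def signed_spectral_clustering(W, K: int, seed: int = 0, n_init: int = 20) -> ModulePartition:
    """Partition a signed network into K modules.

    Steps: signed degree matrix; signed normalized Laplacian; eigenvectors of
    the K smallest eigenvalues stacked column-wise into U; each row of U
    scaled to unit length (all-zero rows are left as zero); k-means with K
    clusters on the rows.  k-means uses k-means++ with ``n_init`` restarts
    and is deterministic for a fixed seed.
    """
    A = _as_matrix(W)
    m = A.shape[0]
    if not (2 <= K <= m):
        raise ValueError(f"K must be in [2, m={m}], got {K}")
    lap = signed_normalized_laplacian(A)
    _, U = scipy.linalg.eigh(lap.L, subset_by_index=[0, K - 1])
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    F = np.where(norms > 0, U / np.where(norms > 0, norms, 1.0), U)
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    labels = km.fit_predict(F)
    return ModulePartition(labels, K, seed)


def sncut(W, P: ModulePartition) -> float:
    """Signed normalized cut of partition P on network W.

    sNcut = sum_k (x_k' L x_k) / (x_k' D x_k) over the K module indicator
    vectors x_k.  Invariant to relabelling the modules.
    """
    A = _as_matrix(W)
    if P.n_nodes != A.shape[0]:
        raise ValueError("partition does not match network size")
    if np.any(P.sizes() == 0):
        raise ValueError("partition has an empty module")
    lap = signed_normalized_laplacian(A)
    total = 0.0
    for k in range(P.K):
        x = (P.labels == k).astype(float)
        num = x @ lap.L @ x
        den = x @ (lap.degrees * x)
        total += num / den
    return float(total)


def consensus_partition(Ws, K: int, seed: int = 0) -> ModulePartition:
    """Cluster the element-wise mean of several networks over one node set.

    The mean matrix is the group-representative network (e.g., the average of
    the normal-control FBNs); its partition defines the modules used for all
    subjects.  Order of the input list is irrelevant.
    """
    mats = [_as_matrix(W) for W in Ws]
    if not mats:
        raise ValueError("need at least one network")
    m = mats[0].shape[0]
    ids = None
    for W in Ws:
        if isinstance(W, ConnectivityMatrix):
            if ids is None:
                ids = W.region_ids
            elif W.region_ids != ids:
                raise ValueError("networks have mismatched node sets")
    if any(M.shape[0] != m for M in mats):
        raise ValueError("networks have mismatched node sets")
    mean_W = np.mean(mats, axis=0)
    return signed_spectral_clustering(mean_W, K, seed)
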