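"""Node-level and global statistics of weighted signed networks.

All statistics are computed on absolute edge weights |w| — the same
absolutization as the signed degree — because the standard weighted-graph
definitions assume nonnegative weights.  Path-based statistics (betweenness,
closeness) use distance = 1/|w|, so strong connections are short.

Statistics: LCC (local clustering coefficient), DC (degree centrality, equal
to the signed degree), BC (betweenness), CC (closeness), EC (eigenvector
centrality).  The global clustering coefficient is the mean LCC over nodes.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .modules import _as_matrix, signed_degree

__all__ = ["node_statistics", "global_clustering", "NODE_STATISTICS"]

NODE_STATISTICS = ("LCC", "DC", "BC", "CC", "EC")


def _abs_graph(W) -> nx.Graph:
    A = np.abs(_as_matrix(W))
    G = nx.from_numpy_array(A)
    # drop numerically-zero edges; they are non-edges for path statistics
    zero = [(u, v) for u, v, d in G.edges(data=True) if d["weight"] <= 1e-15]
    G.remove_edges_from(zero)
    for _, _, d in G.edges(data=True):
        d["distance"] = 1.0 / d["weight"]
    return G


def node_statistics(W, tag: str) -> np.ndarray:
    """One weighted statistic per node, on |W|."""
    tag = tag.upper()
    if tag not in NODE_STATISTICS:
        raise ValueError(f"unknown statistic {tag!r}; choose from {NODE_STATISTICS}")
    A = _as_matrix(W)
    m = A.shape[0]
    if tag == "DC":
        return signed_degree(A)
    G = _abs_graph(A)
    if tag == "LCC":
        vals = nx.clustering(G, weight="weight")
    elif tag == "BC":
        vals = nx.betweenness_centrality(G, weight="distance", normalized=True)
    elif tag == "CC":
        # harmonic-style handling of disconnection: per-component closeness
        vals = nx.closeness_centrality(G, distance="distance")
    else:  # EC
        vals = nx.eigenvector_centrality_numpy(G, weight="weight")
    return np.array([vals[i] for i in range(m)])


def global_clustering(W) -> float:
    """Mean local clustering coefficient over all nodes."""
    return float(node_statistics(W, "LCC").mean())
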