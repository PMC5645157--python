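"""Scalar and per-node network measures shared by all analyses.

Conventions (fixed across the package, with flags where noted):

* wiring cost ``l_p`` sums the Euclidean length of every *directed* link,
  so a reciprocal pair contributes its distance twice;
* graph length ``l_g = 1 / e_g`` with ``e_g`` the mean inverse *directed*
  shortest-path length over ordered pairs (unreachable pairs contribute 0);
* clustering, matching index and similarity operate on the symmetrized
  graph; betweenness stays directed.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from cortnet._graph import efficiency_from_dist, hop_distances, symmetrize


def wiring_cost(A: np.ndarray, D: np.ndarray) -> float:
    """Total wiring length: sum of distances over all directed links."""
    A = np.asarray(A)
    D = np.asarray(D)
    if A.shape != D.shape:
        raise ValueError(f"shape mismatch: A {A.shape} vs D {D.shape}")
    return float((A * D).sum())


def edge_lengths(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Euclidean length of each directed link (mm)."""
    A = np.asarray(A, dtype=bool)
    if A.shape != D.shape:
        raise ValueError("shape mismatch")
    return np.asarray(D)[A]


def global_efficiency(A: np.ndarray) -> float:
    """Mean inverse directed shortest-path length over ordered pairs."""
    return efficiency_from_dist(hop_distances(A))


def graph_length(A: np.ndarray) -> tuple[float, float]:
    """Graph length l_g = 1/e_g and the global efficiency e_g.

    Raises ValueError when the graph has no reachable pairs at all
    (e_g = 0), where l_g is undefined.
    """
    eg = global_efficiency(A)
    if eg == 0.0:
        raise ValueError("global efficiency is 0: graph length undefined")
    return 1.0 / eg, eg


def clustering_coefficients(A: np.ndarray, directed: bool = False) -> np.ndarray:
    """Per-node clustering coefficient.

    Default: fraction of a node's neighbor pairs that are connected, on the
    symmetrized graph (degree < 2 nodes get 0). ``directed=True`` switches
    to the directed (Fagiolo) variant.
    """
    if directed:
        G = nx.from_numpy_array(np.asarray(A).T, create_using=nx.DiGraph)
        return np.array([nx.clustering(G, i) for i in G.nodes])
    B = symmetrize(A).astype(np.int64)
    deg = B.sum(axis=1)
    # triangles through each node = diag(B^3) / 2
    tri = np.diagonal(B @ B @ B) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def betweenness_centrality(A: np.ndarray) -> np.ndarray:
    """Shortest-path betweenness on the directed unweighted graph
    (raw path counts, not normalized)."""
    G = nx.from_numpy_array(np.asarray(A).T, create_using=nx.DiGraph)
    bc = nx.betweenness_centrality(G, normalized=False)
    return np.array([bc[i] for i in range(A.shape[0])])


def matching_index(A: np.ndarray) -> np.ndarray:
    """Neighbor-set overlap K(u, v) = |N(u) & N(v)| / |N(u) | N(v)|.

    Neighbor sets are symmetrized and exclude u and v themselves; 0/0 is
    defined as 0.
    """
    B = symmetrize(A)
    Bi = B.astype(np.int64)
    common = Bi @ Bi          # w != u, v automatically (diag(B) = 0)
    deg = Bi.sum(axis=1)
    # |N(u)\{v}| + |N(v)\{u}| - common
    union = (deg[:, None] - Bi) + (deg[None, :] - Bi) - common
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(union > 0, common / union, 0.0)
    return K


def similarity_matrix(A: np.ndarray) -> np.ndarray:
    """Connectivity similarity S_ij = M_ij / (K_i + K_j - M_ij).

    M_ij counts common symmetrized neighbors and K_i is the symmetrized
    degree, so S is the Jaccard overlap of neighbor sets. Symmetric, in
    [0, 1], diagonal set to 1.
    """
    Bi = symmetrize(A).astype(np.int64)
    M = Bi @ Bi
    deg = Bi.sum(axis=1)
    denom = deg[:, None] + deg[None, :] - M
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(denom > 0, M / denom, 0.0)
    np.fill_diagonal(S, 1.0)
    return S
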