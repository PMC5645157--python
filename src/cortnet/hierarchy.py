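"""Hierarchical segregation/integration analysis.

An agglomerative dendrogram is built from the connectivity dissimilarity
``1 - S`` (S = Jaccard similarity of symmetrized neighbor sets).  Cutting
the tree top-down yields partitions whose Newman modularity is scanned
across thresholds; subtrees dominated (> 0.5) by one functional system
with more than 3 members from that system are retained as function-matched
connectivity modules.  Integration is quantified by the per-area diversity
entropy over the five systems and the dense-group index theta of a node
set versus degree-preserving nulls.  The R-network surrogate rewires the
unrecovered links of the LDC set while preserving the real network's link
distance distribution (hence its total wiring cost).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from cortnet.data import SYSTEMS, UNKNOWN, NullEnsemble, SpatialNetwork
from cortnet.metrics import similarity_matrix


@dataclass
class Dendrogram:
    """Agglomerative merge tree over areas on dissimilarity 1 - S."""

    Z: np.ndarray                # scipy linkage matrix
    method: str
    n: int

    def cut(self, threshold: float) -> np.ndarray:
        """Flat cluster labels after cutting all merges above threshold."""
        return fcluster(self.Z, t=threshold, criterion="distance")

    @property
    def max_height(self) -> float:
        return float(self.Z[:, 2].max()) if len(self.Z) else 0.0


@dataclass
class Subtree:
    members: np.ndarray          # area indices
    dominant: str
    fraction: float
    threshold: float


@dataclass
class SubtreeReport:
    subtrees: list[Subtree]
    non_cluster: np.ndarray

    @property
    def coverage(self) -> float:
        n_in = sum(len(t.members) for t in self.subtrees)
        return n_in / (n_in + len(self.non_cluster))


@dataclass
class DenseGroupResult:
    theta: float
    null_mean: float
    null_std: float

    @property
    def z(self) -> float:
        if self.null_std == 0:
            return np.nan
        return (self.theta - self.null_mean) / self.null_std


def build_dendrogram(A: np.ndarray, method: str = "single") -> Dendrogram:
    """Hierarchical tree from the dissimilarity 1 - S_ij.

    Single linkage is the default (average linkage available through
    ``method``); identical-neighborhood twins merge at height 0.
    """
    A = np.asarray(A)
    n = A.shape[0]
    if n < 2:
        raise ValueError("need at least two areas")
    S = similarity_matrix(A)
    dis = 1.0 - S
    np.fill_diagonal(dis, 0.0)
    Z = linkage(squareform(dis, checks=False), method=method)
    return Dendrogram(Z=Z, method=method, n=n)


def modularity_scan(
    A: np.ndarray,
    dend: Dendrogram,
    thresholds: np.ndarray,
) -> np.ndarray:
    """Newman modularity of the tree-cut partition at each threshold,
    evaluated on the symmetrized binary graph."""
    B = np.asarray(A, dtype=bool)
    B = B | B.T
    np.fill_diagonal(B, False)
    G = nx.from_numpy_array(B.astype(int))
    Q = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        labels = dend.cut(t)
        comms = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
        if G.number_of_edges() == 0:
            Q[i] = 0.0
        else:
            Q[i] = nx.algorithms.community.modularity(G, comms)
    return Q


def extract_subtrees(
    dend: Dendrogram,
    labels: np.ndarray,
    step: float = 0.01,
    dominance: float = 0.5,
    min_dominant: int = 3,
) -> SubtreeReport:
    """Top-down function-matched subtree extraction.

    The tree is cut at descending thresholds (from 1, i.e. above the root,
    towards 0 in steps of ``step``).  Whenever a cluster of not-yet-retained
    areas has a dominant functional system with fraction > ``dominance``
    and more than ``min_dominant`` members from that system, the cluster is
    frozen as a subtree and not divided further.  Areas never captured end
    up in the non-cluster remainder.
    """
    labels = np.asarray(labels, dtype=object)
    if (labels == UNKNOWN).all():
        raise ValueError("no functional labels available")
    n = dend.n
    assigned = np.zeros(n, dtype=bool)
    subtrees: list[Subtree] = []
    top = max(1.0, dend.max_height)
    thresholds = np.arange(top, -step / 2, -step)
    for t in thresholds:
        part = dend.cut(t)
        for c in np.unique(part):
            members = np.flatnonzero(part == c)
            if len(members) < 2 or assigned[members].any():
                continue
            labs = labels[members]
            counts = {s: int((labs == s).sum()) for s in SYSTEMS}
            dom = max(counts, key=counts.get)
            frac = counts[dom] / len(members)
            if frac > dominance and counts[dom] > min_dominant:
                subtrees.append(Subtree(
                    members=members, dominant=dom,
                    fraction=frac, threshold=float(t)))
                assigned[members] = True
    return SubtreeReport(subtrees=subtrees,
                         non_cluster=np.flatnonzero(~assigned))


def diversity_coefficient(net: SpatialNetwork) -> dict:
    """Per-area entropy of the pooled link distribution over the five
    functional systems.

    p_i(J) = k_iJ / k_i with k_iJ the number of the area's (input+output)
    links to system J and k_i the total over the five systems. C_i in
    [0, ln 5]; areas with no links to labeled systems get NaN.
    """
    A = net.A.astype(bool)
    labels = np.asarray(net.system, dtype=object)
    n = net.n_areas
    p = np.zeros((n, len(SYSTEMS)))
    for j, s in enumerate(SYSTEMS):
        in_s = labels == s
        p[:, j] = (A[:, in_s].sum(1) + A[in_s, :].sum(0))
    k = p.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_norm = np.where(k[:, None] > 0, p / np.maximum(k[:, None], 1), 0.0)
        logp = np.where(p_norm > 0, np.log(p_norm), 0.0)
    C = -(p_norm * logp).sum(axis=1)
    C[k == 0] = np.nan
    return {"C": C, "p": p_norm, "k": k}


def dense_group(
    A: np.ndarray,
    node_set,
    null: NullEnsemble,
) -> DenseGroupResult:
    """Internal link density theta of a node set versus the null ensemble.

    theta = (directed links within the set) / (m (m - 1)); the same index
    computed for the identical node set in every null member provides the
    benchmark mean and standard deviation.  Computing theta for the
    top-degree nodes gives the conventional rich-club index.
    """
    nodes = np.asarray(list(node_set), dtype=int)
    if len(nodes) < 2:
        raise ValueError("node set must contain at least 2 nodes")
    m = len(nodes)

    def theta_of(M):
        sub = np.asarray(M, dtype=bool)[np.ix_(nodes, nodes)]
        return sub.sum() / (m * (m - 1))

    theta = float(theta_of(A))
    null_thetas = np.array([theta_of(mem) for mem in null.members])
    return DenseGroupResult(
        theta=theta,
        null_mean=float(null_thetas.mean()),
        null_std=float(null_thetas.std(ddof=0)),
    )


def group_projection_shares(
    A: np.ndarray,
    node_set,
    report: SubtreeReport,
) -> dict:
    """Distribution of the set's external links over retained subtrees.

    External links have exactly one endpoint in the set; each is attributed
    to the subtree (or the non-cluster remainder) containing its outside
    endpoint. Shares sum to 1 when external links exist.
    """
    A = np.asarray(A, dtype=bool)
    n = A.shape[0]
    mask = np.zeros(n, dtype=bool)
    mask[np.asarray(list(node_set), dtype=int)] = True
    external = A & (mask[:, None] ^ mask[None, :])
    tgt, src = np.nonzero(external)
    outside = np.where(mask[src], tgt, src)
    total = len(outside)
    shares = {}
    for idx, tree in enumerate(report.subtrees):
        in_tree = np.isin(outside, tree.members)
        shares[f"tree{idx + 1}_{tree.dominant}"] = (
            float(in_tree.sum() / total) if total else 0.0)
    in_nc = np.isin(outside, report.non_cluster)
    shares["non_cluster"] = float(in_nc.sum() / total) if total else 0.0
    return shares


def build_rnetwork(
    net: SpatialNetwork,
    A_recon: np.ndarray,
    ldcs,
    D: np.ndarray,
    bin_width: float = 5.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Rewire the unrecovered LDC links, preserving the distance histogram.

    Every real link touching an LDC that is absent from the reconstruction
    is replaced by a random currently-unconnected ordered pair whose
    distance falls in the same ``bin_width`` histogram bin (nearest
    non-empty bin as a logged fallback), so the total link count and the
    per-bin link distance distribution -- hence the wiring cost up to bin
    resolution -- are conserved while the concentration of long links on
    the LDCs is destroyed.
    """
    rng = np.random.default_rng(rng)
    A = net.A.copy().astype(np.int8)
    A_recon = np.asarray(A_recon, dtype=bool)
    D = np.asarray(D)
    n = A.shape[0]
    mask = np.zeros(n, dtype=bool)
    ldcs = np.asarray(list(ldcs), dtype=int)
    if len(ldcs):
        mask[ldcs] = True
    unrec = (A.astype(bool) & ~A_recon
             & (mask[:, None] | mask[None, :]))
    tgt, src = np.nonzero(unrec)
    order = rng.permutation(len(tgt))
    n_moved = 0
    n_fallback = 0
    edges_bins = np.arange(0.0, D.max() + bin_width, bin_width)
    for i in order:
        t, s = tgt[i], src[i]
        b = np.digitize(D[t, s], edges_bins) - 1
        A[t, s] = 0
        # candidate non-links in the same distance bin
        placed = False
        for db in sorted(range(len(edges_bins) - 1), key=lambda x: abs(x - b)):
            lo, hi = edges_bins[db], edges_bins[db + 1]
            cand = ((A == 0) & (D >= lo) & (D < hi))
            np.fill_diagonal(cand, False)
            ct, cs = np.nonzero(cand)
            if len(ct) == 0:
                continue
            pick = rng.integers(0, len(ct))
            A[ct[pick], cs[pick]] = 1
            placed = True
            if db != b:
                n_fallback += 1
            break
        if not placed:  # cannot happen unless the graph is complete
            A[t, s] = 1
            continue
        n_moved += 1
    return A, {"n_moved": n_moved, "n_fallback": n_fallback}
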