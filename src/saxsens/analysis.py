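"""Characterization of a weighted conformational ensemble.

Free-energy profile over the radius of gyration, compact/extended
partition, weighted PCA of Cα coordinates, weighted quality-threshold
clustering, conformational space network, and weighted residue-contact
analysis.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np

from .ensemble import AtomEnsemble
from .maxent import KT_300K

__all__ = [
    "ClusterSet",
    "free_energy_profile",
    "partition_by_rg",
    "weighted_pca",
    "qt_cluster",
    "build_network",
    "contact_analysis",
]


def free_energy_profile(rg: np.ndarray, weights: np.ndarray, bins: int = 40,
                        kT: float = KT_300K,
                        range_: tuple[float, float] | None = None):
    """Free-energy profile F = −kT ln p over binned Rg, minimum shifted to 0.

    Returns (bin_centers, free_energy); empty bins are NaN (undefined).
    """
    rg = np.asarray(rg, dtype=float)
    w = np.asarray(weights, dtype=float)
    if bins < 2:
        raise ValueError("need at least 2 bins")
    p, edges = np.histogram(rg, bins=bins, range=range_, weights=w / w.sum())
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        f = np.where(p > 0, -kT * np.log(np.where(p > 0, p, 1.0)), np.nan)
    f = f - np.nanmin(f)
    return centers, f


def partition_by_rg(rg: np.ndarray, weights: np.ndarray,
                    threshold: float) -> tuple[float, float]:
    """Weighted (fraction_compact, fraction_extended) split at an Rg cutoff.

    Compact means Rg ≤ threshold. Fractions sum to 1 and are invariant to
    rescaling the weights. Warns if the threshold misses the observed range.
    """
    rg = np.asarray(rg, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (rg.min() <= threshold <= rg.max()):
        import warnings
        warnings.warn(
            f"Rg threshold {threshold:g} Å outside the observed range "
            f"[{rg.min():.2f}, {rg.max():.2f}] Å — check threshold units",
            stacklevel=2)
    w = w / w.sum()
    compact = float(w[rg <= threshold].sum())
    return compact, 1.0 - compact


def weighted_pca(coords: np.ndarray, weights: np.ndarray | None = None,
                 variance_target: float = 0.93):
    """Weighted PCA of per-frame coordinates (frames, atoms, 3).

    The covariance of the flattened coordinates is weight-averaged; returns
    ``(components, projections, explained, k)`` where ``k`` is the smallest
    number of PCs whose cumulative explained variance reaches
    ``variance_target``, ``projections`` is (frames, n_available) and
    ``explained`` the full normalized spectrum. A degenerate covariance
    simply yields the available components.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames")
    X = coords.reshape(n, -1)
    w = (np.full(n, 1.0 / n) if weights is None
         else np.asarray(weights, dtype=float) / np.sum(weights))
    mu = w @ X
    Xc = X - mu
    cov = (Xc * w[:, None]).T @ Xc
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    nonzero = evals > max(evals[0], 1e-300) * 1e-12
    evals, evecs = evals[nonzero], evecs[:, nonzero]
    explained = evals / evals.sum()
    k = int(np.searchsorted(np.cumsum(explained), variance_target) + 1)
    k = min(k, len(evals))
    projections = Xc @ evecs
    return evecs.T, projections, explained, k


@dataclasses.dataclass
class ClusterSet:
    """QT clustering outcome: per-frame labels, medoids, summed weights."""

    labels: np.ndarray              # per-frame cluster id, dense 0..n_clusters-1
    representatives: np.ndarray     # per-cluster medoid frame index
    cluster_weights: np.ndarray     # per-cluster summed statistical weight
    subset_tag: np.ndarray          # per-cluster tag, e.g. 'compact'/'extended'

    def __post_init__(self):
        for c, rep in enumerate(self.representatives):
            if self.labels[rep] != c:
                raise ValueError(f"representative of cluster {c} not in cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def _qt_rounds(dist: np.ndarray, weights: np.ndarray, cutoff: float):
    """Iteratively extract the maximum-weight subset of diameter ≤ cutoff.

    Each round solves the subproblem exactly: subsets of diameter ≤ cutoff
    are cliques of the 'distance ≤ cutoff' graph, and the heaviest one is
    found with an exact branch-and-bound max-weight-clique search
    (networkx). The winning cluster is removed and the search repeats until
    every point is assigned.
    """
    n = len(weights)
    remaining = list(range(n))
    clusters = []
    adj = dist <= cutoff
    while remaining:
        if len(remaining) == 1:
            clusters.append([remaining[0]])
            break
        g = nx.Graph()
        # integerized weights: nx.max_weight_clique requires numbers; use a
        # fixed-point scale on the weight ratio (in [0, 1] even for
        # denormal weights) so float weights compare exactly; frames whose
        # weight underflowed to 0 still count 1, i.e. ties break by size
        wmax = weights[remaining].max()
        for i in remaining:
            ratio = weights[i] / wmax if wmax > 0 else 0.0
            g.add_node(i, w=int(round(ratio * 10 ** 12)) + 1)
        for ai, i in enumerate(remaining):
            for j in remaining[ai + 1:]:
                if adj[i, j]:
                    g.add_edge(i, j)
        members, _ = nx.algorithms.clique.max_weight_clique(g, weight="w")
        members = sorted(members)
        clusters.append(members)
        chosen = set(members)
        remaining = [i for i in remaining if i not in chosen]
    return clusters


def qt_cluster(dist: np.ndarray, weights: np.ndarray, cutoff: float,
               subset: np.ndarray | None = None) -> ClusterSet:
    """Weighted quality-threshold clustering of a distance matrix.

    Repeatedly extracts the subset with the largest summed weight whose
    diameter (max pairwise distance) stays ≤ ``cutoff``, removes it, and
    continues until every point belongs to a cluster. The representative of
    a cluster is its medoid (minimum summed intra-cluster distance, ties to
    the lowest frame index). With ``subset`` labels (e.g. compact /
    extended) clustering runs separately within each subset, so no cluster
    ever mixes tags.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or not np.allclose(dist, dist.T):
        raise ValueError("dist must be a symmetric square matrix")
    if not np.allclose(np.diag(dist), 0):
        raise ValueError("dist must have a zero diagonal")
    weights = np.asarray(weights, dtype=float)
    subset = (np.zeros(n, dtype=object) if subset is None
              else np.asarray(subset))

    labels = np.full(n, -1, dtype=int)
    reps, cw, tags = [], [], []
    cid = 0
    for tag in np.unique(subset):
        idx = np.nonzero(subset == tag)[0]
        local = _qt_rounds(dist[np.ix_(idx, idx)], weights[idx], cutoff)
        for members_local in local:
            members = idx[np.asarray(members_local)]
            labels[members] = cid
            sub = dist[np.ix_(members, members)]
            reps.append(int(members[np.argmin(sub.sum(axis=1))]))
            cw.append(float(weights[members].sum()))
            tags.append(tag)
            cid += 1
    return ClusterSet(labels=labels, representatives=np.array(reps, dtype=int),
                      cluster_weights=np.array(cw), subset_tag=np.array(tags))


def logistic_size(weights: np.ndarray, midpoint: float | None = None,
                  decade_rate: float = 1.0) -> np.ndarray:
    """Display sizes: logistic rescaling of cluster weights.

    Midpoint defaults to the median weight; the rate is per decade of
    weight, so s(w) = 1 / (1 + (midpoint / w)^rate). Monotone in w;
    display-only, never used in statistics.
    """
    w = np.asarray(weights, dtype=float)
    mid = float(np.median(w)) if midpoint is None else midpoint
    return 1.0 / (1.0 + (mid / np.maximum(w, 1e-300)) ** decade_rate)


def build_network(clusters: ClusterSet, rep_dist: np.ndarray,
                  edge_cutoff: float = 5.0, midpoint: float | None = None,
                  decade_rate: float = 1.0) -> nx.Graph:
    """Conformational space network over cluster representatives.

    One node per cluster carrying its weight, subset tag and
    logistic-rescaled display size; edges join clusters whose
    representative distance is ≤ ``edge_cutoff``. No self-edges.
    """
    k = clusters.n_clusters
    rep_dist = np.asarray(rep_dist, dtype=float)
    if rep_dist.shape != (k, k):
        raise ValueError("rep_dist must be n_clusters x n_clusters")
    sizes = logistic_size(clusters.cluster_weights, midpoint, decade_rate)
    g = nx.Graph()
    for c in range(k):
        g.add_node(c, weight=float(clusters.cluster_weights[c]),
                   subset=str(clusters.subset_tag[c]), size=float(sizes[c]),
                   representative=int(clusters.representatives[c]))
    for a in range(k):
        for b in range(a + 1, k):
            if rep_dist[a, b] <= edge_cutoff:
                g.add_edge(a, b, distance=float(rep_dist[a, b]))
    return g


def contact_analysis(ens: AtomEnsemble, weights: np.ndarray,
                     group_a, group_b, cutoff: float = 5.0,
                     persistence: float = 0.025):
    """Weighted residue–residue contact statistics (closest-heavy scheme).

    ``group_a``/``group_b`` are disjoint iterables of (chain, resid). A
    pair is in contact in a frame iff the minimum heavy-atom distance is
    below ``cutoff`` Å; its probability is the weighted fraction of contact
    frames, and pairs above the ``persistence`` probability threshold are
    flagged persistent. Also returns the per-residue weighted mean number
    of partner residues in contact.

    Returns a dict with 'pairs' (list of ((chain_a, res_a), (chain_b,
    res_b), probability, persistent)) and 'residue_counts'
    ({(chain, resid): weighted mean partner count}).
    """
    group_a = [tuple(x) for x in group_a]
    group_b = [tuple(x) for x in group_b]
    if set(group_a) & set(group_b):
        raise ValueError("residue groups must be disjoint")
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()

    heavy = ens.elements != "H"

    def atoms_of(res):
        chain, rid = res
        m = heavy & (ens.chain_ids == chain) & (ens.residue_ids == int(rid))
        idx = np.nonzero(m)[0]
        if idx.size == 0:
            raise ValueError(f"residue {chain}{rid} has no heavy atoms")
        return idx

    idx_a = [atoms_of(r) for r in group_a]
    idx_b = [atoms_of(r) for r in group_b]

    # contact[f, i, j]: pair (a_i, b_j) in contact in frame f
    contact = np.zeros((ens.n_frames, len(group_a), len(group_b)), dtype=bool)
    for i, ia in enumerate(idx_a):
        for j, jb in enumerate(idx_b):
            d = ens.coords[:, ia, None, :] - ens.coords[:, None, jb, :]
            dmin = np.sqrt((d ** 2).sum(axis=3)).min(axis=(1, 2))
            contact[:, i, j] = dmin < cutoff

    prob = np.einsum("f,fij->ij", w, contact)
    pairs = [(group_a[i], group_b[j], float(prob[i, j]),
              bool(prob[i, j] > persistence))
             for i in range(len(group_a)) for j in range(len(group_b))]

    counts = {}
    for i, res in enumerate(group_a):
        counts[res] = float(np.einsum("f,fj->", w, contact[:, i, :]))
    for j, res in enumerate(group_b):
        counts[res] = float(np.einsum("f,fi->", w, contact[:, :, j]))
    return {"pairs": pairs, "residue_counts": counts}
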