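"""Protein families via Markov Clustering and the shared-cluster statistic.

Aligned proteins are clustered with MCL (alternating expansion — a matrix
power — and inflation — an elementwise power with column renormalization —
on the column-stochastic adjacency matrix with self-loops). Clusters with a
single member are discarded. Two phages are then scored by the
hypergeometric tail probability Q(N >= c) of sharing at least c retained
clusters by chance, given the number of retained clusters each touches and
the total number of retained clusters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Set

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln

from .evidence import GeneCatalog, ProteinGraph


@dataclass
class ClusterAssignment:
    """Partition of proteins into clusters; singletons are not retained."""

    cluster_of: Dict[str, int]
    retained_clusters: Set[int] = field(default_factory=set)
    converged: bool = True

    def __post_init__(self) -> None:
        sizes: Dict[int, int] = {}
        for cid in self.cluster_of.values():
            sizes[cid] = sizes.get(cid, 0) + 1
        expected = {cid for cid, n in sizes.items() if n >= 2}
        if not self.retained_clusters:
            self.retained_clusters = expected


def mcl_cluster(
    protein_graph: ProteinGraph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ClusterAssignment:
    """Markov Clustering of the protein similarity graph.

    Self-loops of weight 1 are added, columns are normalized, and the
    expansion/inflation cycle iterates until the largest column-wise change
    drops below `tol` or `max_iter` is reached (then the current clustering
    is returned with a warning). Clusters are the connected components of
    the thresholded converged matrix, which coincide with its attractor
    systems; component labels follow the lowest-indexed member.
    """
    if not protein_graph.nodes:
        raise ValueError("empty protein graph")
    if inflation <= 1:
        raise ValueError(f"inflation must be > 1, got {inflation}")
    nodes = protein_graph.nodes
    ix = {pid: i for i, pid in enumerate(nodes)}
    n = len(nodes)
    mat = np.eye(n)
    for (a, b), w in protein_graph.edges.items():
        if a == b:
            continue
        mat[ix[a], ix[b]] = w
        mat[ix[b], ix[a]] = w
    mat /= mat.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        new = np.linalg.matrix_power(mat, expansion)
        new = new**inflation
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new /= colsum
        delta = np.abs(new - mat).max()
        mat = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge within {max_iter} iterations")
    support = (mat > max(tol, 1e-8)) | (mat.T > max(tol, 1e-8))
    n_comp, labels = connected_components(support, directed=False)
    # relabel components by their lowest-indexed member for determinism
    first_member: Dict[int, int] = {}
    for i, lab in enumerate(labels):
        first_member.setdefault(int(lab), i)
    relabel = {lab: rank for rank, lab in enumerate(
        sorted(first_member, key=first_member.get))}
    cluster_of = {nodes[i]: relabel[int(labels[i])] for i in range(n)}
    assignment = ClusterAssignment(cluster_of=cluster_of, converged=converged)
    return assignment


def shared_cluster_probability(c: int, x: int, y: int, n: int) -> float:
    """Hypergeometric tail Q(N >= c): chance of sharing at least c clusters.

    x and y are the cluster counts of the two phages, n the total number of
    retained clusters. Computed by log-space summation of
    C(x,i) * C(n-x, y-i) / C(n,y) for i = c .. min(x,y); impossible
    configurations contribute nothing.
    """
    if x < 0 or y < 0 or n < 0 or c < 0:
        raise ValueError("c, x, y, n must be non-negative")
    if x > n or y > n:
        raise ValueError(f"x={x} and y={y} must not exceed n={n}")
    hi = min(x, y)
    if c > hi:
        return 0.0
    if c <= 0:
        return 1.0
    log_denom = _log_comb(n, y)
    total = 0.0
    for i in range(c, hi + 1):
        if y - i > n - x:
            continue
        total += math.exp(_log_comb(x, i) + _log_comb(n - x, y - i) - log_denom)
    return min(total, 1.0)


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


@dataclass(frozen=True)
class SharedClusterStat:
    """Shared-cluster statistic for one unordered phage pair."""

    phage_a: str
    phage_b: str
    c: int
    x: int
    y: int
    n: int
    q: float


def phage_pair_stats(
    assignment: ClusterAssignment,
    catalog: GeneCatalog,
    protein_graph: ProteinGraph,
    xy_mode: str = "clusters",
) -> List[SharedClusterStat]:
    """Per-pair shared-cluster counts and tail probabilities.

    By default x and y count the distinct retained clusters touched by each
    phage (clamped to n), which keeps the hypergeometric support coherent;
    ``xy_mode="proteins"`` switches to raw per-phage protein counts.
    """
    if xy_mode not in ("clusters", "proteins"):
        raise ValueError(f"unknown xy_mode {xy_mode!r}")
    unassigned = [p for p in protein_graph.nodes if p not in assignment.cluster_of]
    if unassigned:
        raise ValueError(f"proteins missing from cluster assignment: {unassigned[:5]}")
    retained = assignment.retained_clusters
    n = len(retained)
    clusters_of_phage: Dict[str, Set[int]] = {acc: set() for acc in catalog}
    for pid, cid in assignment.cluster_of.items():
        if cid in retained:
            clusters_of_phage[protein_graph.owner[pid]].add(cid)
    stats: List[SharedClusterStat] = []
    accs = sorted(catalog)
    for i, a in enumerate(accs):
        for b in accs[i + 1 :]:
            c = len(clusters_of_phage[a] & clusters_of_phage[b])
            if xy_mode == "clusters":
                x = len(clusters_of_phage[a])
                y = len(clusters_of_phage[b])
            else:
                x = min(len(catalog[a]), n)
                y = min(len(catalog[b]), n)
            q = shared_cluster_probability(c, x, y, n) if n > 0 else 1.0
            stats.append(SharedClusterStat(a, b, c, x, y, n, q))
    return stats
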