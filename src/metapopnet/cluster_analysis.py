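"""Cluster detection on symmetrized dispersal flows.

Between-population flows are symmetrized (``S[i, j] = W[i, j] + W[j, i]``,
within-population events excluded), hierarchically clustered by average
linkage on similarities (UPGMA: the most similar pair of clusters merges
first, cluster-cluster similarity is the mean of cross-pair similarities),
and the dendrogram is cut at every merge level. Each cut is scored with the
weighted Newman-Girvan modularity

    Q = sum_k (e_kk - a_k^2)

where e_kk is the fraction of total weight inside cluster k and a_k the
fraction attached to cluster k; the cut with maximal Q is reported (ties go
to the cut with fewer clusters). Q of the one-cluster partition is exactly 0;
Q > 0.3 is the conventional bar for a useful division. The dendrogram is
validated by the cophenetic correlation coefficient (CCC): the Pearson
correlation between off-diagonal similarities and the merge heights at which
pairs join, with CCC > 0.8 read as a faithful summary of the matrix.

Restricting modularity to dendrogram cuts (rather than free optimisation)
keeps Q and the CCC referring to the same tree, mirroring how association
matrices are clustered in social-network packages for animal data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .network_builder import DispersalNetwork

__all__ = [
    "Dendrogram",
    "ClusterResult",
    "symmetrize_excluding_self",
    "average_linkage_dendrogram",
    "cophenetic_correlation",
    "max_modularity_partition",
    "modularity",
    "out_in_ratios",
    "analyze_clusters",
]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over named leaves.

    ``merges`` lists n-1 merges as ``(left_id, right_id, height)`` where ids
    0..n-1 are leaves and n+k is the cluster created by merge k; heights are
    linkage *similarities*, monotone non-increasing along the merge sequence.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError("a dendrogram over n leaves needs n-1 merges")

    def members(self) -> list[set[int]]:
        """Leaf-index membership of every node id (leaves then internal nodes)."""
        n = len(self.leaves)
        out: list[set[int]] = [{i} for i in range(n)]
        for a, b, _ in self.merges:
            out.append(out[a] | out[b])
        return out

    def cuts(self) -> list[list[set[int]]]:
        """All partitions induced by the merge sequence.

        Element m is the partition after m merges: from all-singletons (m=0)
        to the single cluster (m = n-1).
        """
        n = len(self.leaves)
        members = self.members()
        active = {i for i in range(n)}
        parts = [[set(members[i]) for i in sorted(active)]]
        for k, (a, b, _) in enumerate(self.merges):
            active -= {a, b}
            active.add(n + k)
            parts.append([set(members[i]) for i in sorted(active)])
        return parts

    def cophenetic_matrix(self) -> np.ndarray:
        """C[i, j] = similarity height at which leaves i and j first share a cluster."""
        n = len(self.leaves)
        members = self.members()
        C = np.zeros((n, n))
        for k, (a, b, h) in enumerate(self.merges):
            for i in members[a]:
                for j in members[b]:
                    C[i, j] = C[j, i] = h
        return C

    def to_newick(self) -> str:
        """Ultrametric Newick string with branch lengths derived from merge heights.

        Heights are similarities (larger = merged earlier); leaves sit at the
        maximum merge similarity, the root at the minimum, and a branch's
        length is the similarity drop between child and parent node.
        """
        if not self.merges:
            return f"{self.leaves[0]};" if self.leaves else ";"
        n = len(self.leaves)
        hmax = max(h for _, _, h in self.merges)

        def level(i: int) -> float:
            return hmax if i < n else self.merges[i - n][2]

        def render(i: int, parent_level: float) -> str:
            bl = max(level(i) - parent_level, 0.0)
            if i < n:
                return f"{_escape(self.leaves[i])}:{bl:.6g}"
            a, b, _ = self.merges[i - n]
            return f"({render(a, level(i))},{render(b, level(i))}):{bl:.6g}"

        root = n + len(self.merges) - 1
        a, b, _ = self.merges[-1]
        return f"({render(a, level(root))},{render(b, level(root))});"


def _escape(name: str) -> str:
    if any(c in name for c in "(),:; '\t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name


@dataclass(frozen=True)
class ClusterResult:
    """Max-modularity partition of a dispersal network with its diagnostics.

    ``partition`` maps population name to cluster id; ``out_in`` (and the
    underlying in/out counts of *outgoing* events) are only defined for
    populations in multi-member clusters, with ``None`` marking an undefined
    ratio (no within-cluster outgoing events).
    """

    partition: dict[str, int]
    q_max: float
    ccc: Optional[float]
    out_in: dict[str, Optional[float]] = field(default_factory=dict)
    in_counts: dict[str, int] = field(default_factory=dict)
    out_counts: dict[str, int] = field(default_factory=dict)
    dendrogram: Optional[Dendrogram] = None
    linkage: str = "average"

    @property
    def n_clusters(self) -> int:
        return len(set(self.partition.values()))

    def clusters(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for name, cid in self.partition.items():
            out.setdefault(cid, []).append(name)
        return [out[c] for c in sorted(out)]


def symmetrize_excluding_self(network: DispersalNetwork) -> np.ndarray:
    """Symmetric exchange matrix S = W + W^T; self events never enter."""
    W = np.asarray(network.W, dtype=float)
    return W + W.T


_LINKAGES = {
    "average": np.mean,
    "single": np.max,  # on similarities, single linkage keeps the closest pair
    "complete": np.min,
}


def average_linkage_dendrogram(
    S: np.ndarray, leaves: Sequence[str] | None = None, linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of a symmetric non-negative similarity matrix.

    Merges the pair of clusters with the highest linkage similarity at each
    step; ties are broken toward the lexicographically smallest pair of
    cluster labels (a cluster's label is the sorted tuple of its leaf names),
    which makes the tree deterministic. ``linkage`` may be ``average``
    (UPGMA, the default), ``single`` or ``complete`` for sensitivity checks.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.ndim != 2 or S.shape[1] != n:
        raise ValueError("S must be square")
    if n < 2:
        raise ValueError("need at least 2 leaves to cluster")
    if not np.allclose(S, S.T):
        raise ValueError("S must be symmetric")
    if np.any(S < 0):
        raise ValueError("S must be non-negative")
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    agg = _LINKAGES[linkage]
    if leaves is None:
        leaves = tuple(str(i) for i in range(n))
    leaves = tuple(leaves)
    if len(leaves) != n:
        raise ValueError("leaf names do not match matrix size")

    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    labels: dict[int, tuple[str, ...]] = {i: (leaves[i],) for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(members) > 1:
        best = None
        for a, b in itertools.combinations(sorted(members), 2):
            sim = agg([S[i, j] for i in members[a] for j in members[b]])
            pair_label = tuple(sorted((labels[a], labels[b])))
            key = (-sim, pair_label)
            if best is None or key < best[0]:
                best = (key, a, b, sim)
        _, a, b, sim = best
        merges.append((a, b, float(sim)))
        members[next_id] = members.pop(a) | members.pop(b)
        labels[next_id] = tuple(sorted(labels.pop(a) + labels.pop(b)))
        next_id += 1
    return Dendrogram(leaves, tuple(merges))


def cophenetic_correlation(dendrogram: Dendrogram, S: np.ndarray) -> Optional[float]:
    """Pearson correlation between off-diagonal similarities and cophenetic heights.

    Returns ``None`` (with a warning) when either vector has zero variance,
    where the coefficient is undefined.
    """
    S = np.asarray(S, dtype=float)
    n = len(dendrogram.leaves)
    if S.shape != (n, n):
        raise ValueError("S does not match the dendrogram's leaf set")
    iu = np.triu_indices(n, 1)
    x = S[iu]
    y = dendrogram.cophenetic_matrix()[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("cophenetic correlation undefined: zero variance", stacklevel=2)
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return r


def modularity(S: np.ndarray, clusters: Sequence[set[int] | Sequence[int]]) -> float:
    """Weighted Newman-Girvan Q of a partition of the similarity matrix's nodes."""
    S = np.asarray(S, dtype=float)
    total = S.sum()
    if total <= 0:
        raise ValueError("total weight of S must be positive")
    q = 0.0
    for cl in clusters:
        idx = sorted(cl)
        e_kk = S[np.ix_(idx, idx)].sum() / total
        a_k = S[idx, :].sum() / total
        q += e_kk - a_k**2
    return q


def max_modularity_partition(
    dendrogram: Dendrogram, S: np.ndarray
) -> tuple[dict[str, int], float, list[float]]:
    """Best dendrogram cut under weighted modularity.

    Evaluates Q at every cut, from the single cluster down to all singletons,
    and returns ``(partition, Q_max, q_by_cut)`` where ``q_by_cut[m]`` is the
    modularity of the partition after m merges. Ties (within 1e-12) resolve
    to the cut with fewer clusters; cluster ids are assigned in leaf order.
    """
    S = np.asarray(S, dtype=float)
    if S.size == 0:
        raise ValueError("empty similarity matrix")
    cuts = dendrogram.cuts()
    q_by_cut = [modularity(S, cut) for cut in cuts]
    best_m = len(cuts) - 1  # one cluster (Q = 0) is the baseline
    for m in range(len(cuts) - 1, -1, -1):
        if q_by_cut[m] > q_by_cut[best_m] + 1e-12:
            best_m = m
    partition: dict[str, int] = {}
    clusters = sorted(cuts[best_m], key=min)
    for cid, cl in enumerate(clusters):
        for i in cl:
            partition[dendrogram.leaves[i]] = cid
    return partition, q_by_cut[best_m], q_by_cut


def out_in_ratios(
    network: DispersalNetwork, partition: dict[str, int]
) -> tuple[dict[str, Optional[float]], dict[str, int], dict[str, int]]:
    """Out/In ratios of outgoing events for populations in multi-member clusters.

    For population i, In is the count of outgoing events to populations in
    its own cluster and Out the count to populations outside it; the ratio is
    Out/In (``None`` when In = 0, 0.0 when only Out = 0). Populations left as
    singletons by the cut are omitted. Returns ``(ratios, in_counts, out_counts)``.
    """
    sizes: dict[int, int] = {}
    for cid in partition.values():
        sizes[cid] = sizes.get(cid, 0) + 1
    ratios: dict[str, Optional[float]] = {}
    in_counts: dict[str, int] = {}
    out_counts: dict[str, int] = {}
    for name, cid in partition.items():
        if sizes[cid] < 2:
            continue
        i = network.index(name)
        inside = sum(
            int(network.W[i, network.index(other)])
            for other, ocid in partition.items()
            if other != name and ocid == cid
        )
        outside = sum(
            int(network.W[i, network.index(other)])
            for other, ocid in partition.items()
            if ocid != cid
        )
        in_counts[name] = inside
        out_counts[name] = outside
        if inside == 0:
            warnings.warn(f"out/in ratio undefined for {name}: no within-cluster events", stacklevel=2)
            ratios[name] = None
        else:
            ratios[name] = outside / inside
    return ratios, in_counts, out_counts


def analyze_clusters(network: DispersalNetwork, linkage: str = "average") -> ClusterResult:
    """Full cluster analysis of one network: symmetrize, cluster, cut, validate."""
    S = symmetrize_excluding_self(network)
    dend = average_linkage_dendrogram(S, network.populations, linkage=linkage)
    partition, q_max, _ = max_modularity_partition(dend, S)
    ccc = cophenetic_correlation(dend, S)
    ratios, in_c, out_c = out_in_ratios(network, partition)
    return ClusterResult(
        partition=partition,
        q_max=q_max,
        ccc=ccc,
        out_in=ratios,
        in_counts=in_c,
        out_counts=out_c,
        dendrogram=dend,
        linkage=linkage,
    )
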