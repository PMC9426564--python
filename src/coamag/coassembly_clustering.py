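"""Coassembly group selection by Ward clustering with a silhouette sweep.

The metagenome distance matrix is clustered with Ward-criterion hierarchical
agglomeration applied directly to the given dissimilarities (the Lance-
Williams update on squared dissimilarities, i.e. the "ward.D2" convention —
no Euclidean embedding is performed).  The dendrogram is then cut at every
k from 2 to n−1 and each partition is scored with the mean silhouette; the
cut maximizing the silhouette defines the coassembly sets.  A "suboptimal"
cut — the silhouette local maximum nearest a user-supplied target group
count — is also available for comparing against an a-priori grouping of a
given size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .kmer_distance import DistanceMatrix


@dataclass
class Dendrogram:
    """Agglomerative merge sequence over n_leaves samples.

    ``merge_steps`` lists (left, right, height, size) in merge order with
    scipy node numbering (leaves 0..n−1, internal nodes n..2n−2); heights
    are non-decreasing under the Ward criterion.
    """

    merge_steps: list[tuple[int, int, float, int]]
    n_leaves: int
    linkage_matrix: np.ndarray = field(repr=False, default=None)  # scipy Z

    def __post_init__(self) -> None:
        if len(self.merge_steps) != self.n_leaves - 1:
            raise ValueError("a dendrogram over n leaves has exactly n-1 merges")


@dataclass
class ClusteringResult:
    """Full silhouette sweep over cut levels plus the selected k."""

    sample_ids: list[str]
    labels_by_k: dict[int, np.ndarray]
    silhouette_by_k: dict[int, float]
    optimal_k: int
    suboptimal_k: int | None = None


@dataclass
class CoassemblyPlan:
    """Partition of the samples into coassembly groups, numbered from 1."""

    groups: dict[int, list[str]]
    source_k: int

    def __post_init__(self) -> None:
        gids = sorted(self.groups)
        if gids != list(range(1, len(gids) + 1)):
            raise ValueError("group ids must be consecutive integers from 1")
        seen: set[str] = set()
        for members in self.groups.values():
            if not members:
                raise ValueError("empty coassembly group")
            overlap = seen.intersection(members)
            if overlap:
                raise ValueError(f"samples in more than one group: {sorted(overlap)}")
            seen.update(members)

    @property
    def sample_ids(self) -> list[str]:
        return [sid for members in self.groups.values() for sid in members]


def ward_cluster(matrix: DistanceMatrix) -> Dendrogram:
    """Ward-criterion agglomeration of the dissimilarity matrix (ward.D2)."""
    matrix.validate()
    if matrix.n < 2:
        raise ValueError("need at least 2 samples to cluster")
    condensed = squareform(matrix.values, checks=False)
    Z = linkage(condensed, method="ward")
    steps = [(int(a), int(b), float(h), int(s)) for a, b, h, s in Z]
    return Dendrogram(merge_steps=steps, n_leaves=matrix.n, linkage_matrix=Z)


def cut_dendrogram(dendro: Dendrogram, k: int) -> np.ndarray:
    """Labels from undoing the last k−1 merges; exactly k clusters."""
    if not 1 <= k <= dendro.n_leaves:
        raise ValueError(f"k={k} outside [1, {dendro.n_leaves}]")
    labels = cut_tree(dendro.linkage_matrix, n_clusters=k).ravel()
    return labels.astype(int)


def mean_silhouette(matrix: DistanceMatrix, labels) -> float:
    """Unweighted mean silhouette of a partition under precomputed distances.

    s(i) = (b(i) − a(i)) / max(a(i), b(i)) with a(i) the mean distance to
    co-members and b(i) the smallest mean distance to another cluster;
    members of singleton clusters score 0 by convention.
    """
    labels = np.asarray(labels)
    n = matrix.n
    if labels.shape != (n,):
        raise ValueError("labels must cover every sample exactly once")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    D = matrix.values
    # per-sample summed distance to each cluster, shape (n, n_clusters)
    member = (labels[:, None] == uniq[None, :]).astype(float)
    sums = D @ member
    sizes = member.sum(axis=0)
    own = np.searchsorted(uniq, labels)
    own_size = sizes[own]
    s = np.zeros(n)
    non_single = own_size > 1
    a = np.zeros(n)
    a[non_single] = sums[non_single, own[non_single]] / (own_size[non_single] - 1)
    other_means = sums / sizes[None, :]
    other_means[np.arange(n), own] = np.inf
    b = other_means.min(axis=1)
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore"):
        s_ns = (b - a) / denom
    s[non_single] = np.where(denom[non_single] > 0, s_ns[non_single], 0.0)
    return float(s.mean())


def find_optimal_clustering(matrix: DistanceMatrix, k_min: int = 2,
                            k_max: int | None = None) -> ClusteringResult:
    """Sweep dendrogram cuts over k ∈ [k_min, k_max] and pick the best.

    The silhouette score is computed for every cut; optimal_k is the argmax
    (smallest k on ties).  The full score curve is retained so the sweep can
    be plotted (k vs mean silhouette).
    """
    n = matrix.n
    if n < 3:
        raise ValueError("need at least 3 samples to sweep k in [2, n-1]")
    if k_max is None:
        k_max = n - 1
    if not 2 <= k_min <= k_max <= n - 1:
        raise ValueError(f"invalid sweep range [{k_min}, {k_max}] for n={n}")
    dendro = ward_cluster(matrix)
    labels_by_k: dict[int, np.ndarray] = {}
    silhouette_by_k: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        labels = cut_dendrogram(dendro, k)
        labels_by_k[k] = labels
        silhouette_by_k[k] = mean_silhouette(matrix, labels)
    ks = sorted(silhouette_by_k)
    scores = np.array([silhouette_by_k[k] for k in ks])
    optimal_k = ks[int(np.argmax(scores))]  # first max -> smallest k on ties
    return ClusteringResult(
        sample_ids=list(matrix.sample_ids),
        labels_by_k=labels_by_k,
        silhouette_by_k=silhouette_by_k,
        optimal_k=optimal_k,
    )


def find_suboptimal_clustering(result: ClusteringResult, target_k: int) -> int:
    """Silhouette local maximum nearest a target group count.

    Among cut levels whose score is ≥ both neighbours' scores (curve ends
    compare against their one neighbour), returns the k minimizing
    |k − target_k|; ties break toward the higher silhouette, then the
    smaller k.  The choice is stored as ``result.suboptimal_k``.
    """
    ks = sorted(result.silhouette_by_k)
    if not ks[0] <= target_k <= ks[-1]:
        raise ValueError(f"target_k={target_k} outside swept range [{ks[0]}, {ks[-1]}]")
    scores = [result.silhouette_by_k[k] for k in ks]
    local_maxima = []
    for i, k in enumerate(ks):
        left_ok = i == 0 or scores[i] >= scores[i - 1]
        right_ok = i == len(ks) - 1 or scores[i] >= scores[i + 1]
        if left_ok and right_ok:
            local_maxima.append(k)
    chosen = min(local_maxima,
                 key=lambda k: (abs(k - target_k), -result.silhouette_by_k[k], k))
    result.suboptimal_k = chosen
    return chosen


def plan_from_labels(sample_ids, labels, k: int | None = None) -> CoassemblyPlan:
    """Turn per-sample labels into a CoassemblyPlan.

    Groups are numbered 1..k in order of first appearance in the label
    sequence, so plans are stable under label permutation.
    """
    labels = list(labels)
    if len(labels) != len(sample_ids):
        raise ValueError("labels and sample_ids must be congruent")
    order: dict = {}
    groups: dict[int, list[str]] = {}
    for sid, lab in zip(sample_ids, labels):
        if lab not in order:
            order[lab] = len(order) + 1
            groups[order[lab]] = []
        groups[order[lab]].append(sid)
    if k is not None and len(groups) != k:
        raise ValueError(f"labels use {len(groups)} groups, expected k={k}")
    return CoassemblyPlan(groups=groups, source_k=len(groups))
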