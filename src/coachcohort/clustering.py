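"""Participant grouping: weighted Manhattan distance + average-linkage merging.

Similarity between two participants u, v is the weighted Manhattan (L1)
distance over their standardized baseline assessment variables,

    d(u, v) = sum_i  w_i * |u_i - v_i| ,

with w_i drawn from the five-level vocabulary {0, 0.5, 1, 1.5, 2} so that
caregivers can emphasise the dimensions that matter for a given question.
Groups are then built by hierarchical agglomerative clustering with average
linkage (UPGMA): at each step the two clusters with the smallest mean
pairwise inter-cluster distance are merged, and the recorded merge height is
that mean.  Cutting the resulting dendrogram at a dissimilarity threshold
yields a flat grouping; tiny groups below ``min_cluster_size`` are flagged as
outliers and conventionally excluded from insight extraction.

The agglomerator is implemented here (rather than delegated) so that merge
heights and tie-breaking are exactly specified: ties on height are broken by
the lexicographically smallest (node-id, node-id) pair.  Node ids follow the
usual linkage convention — leaves 0..n-1, the i-th merge creates node n+i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError


def weighted_manhattan(u, v, w) -> float:
    """Weighted L1 distance over shared (non-NaN) variables.

    ``u``/``v`` are aligned value sequences (may contain NaN for missing);
    ``w`` nonnegative weights.  Missing variables are deleted pairwise and the
    sum rescaled by total_weight/shared_weight so distances stay comparable.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if u.shape != v.shape or u.shape != w.shape:
        raise DataError("weighted_manhattan: u, v and w must be aligned")
    if np.any(w < 0):
        raise ConfigError("weights must be nonnegative")
    shared = ~(np.isnan(u) | np.isnan(v))
    if not np.any(shared):
        raise DataError("participants share no observed variables")
    total_w = float(w.sum())
    shared_w = float(w[shared].sum())
    d = float(np.sum(w[shared] * np.abs(u[shared] - v[shared])))
    if shared_w > 0 and total_w > 0:
        d *= total_w / shared_w
    return d


@dataclass
class DistanceMatrix:
    participant_ids: list[str]
    values: np.ndarray  # (n, n), symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.participant_ids)
        if self.values.shape != (n, n):
            raise DataError("distance matrix shape does not match participant list")
        if not np.all(np.isfinite(self.values)):
            raise DataError("distance matrix contains non-finite entries")
        if np.any(self.values < 0) or np.any(np.diag(self.values) != 0):
            raise DataError("distances must be nonnegative with a zero diagonal")
        if not np.allclose(self.values, self.values.T):
            raise DataError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.participant_ids)


def pairwise_distances(zframe: pd.DataFrame, weights: dict[str, float]) -> DistanceMatrix:
    """All-pairs weighted Manhattan distances from a participant x variable z-frame."""
    if len(zframe) < 2:
        raise DataError("need at least 2 participants to compute distances")
    variables = [c for c in zframe.columns if weights.get(c, 0.0) >= 0]
    w = np.array([weights.get(c, 0.0) for c in variables], dtype=float)
    X = zframe[variables].to_numpy(dtype=float)
    n = len(zframe)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = weighted_manhattan(X[i], X[j], w)
    return DistanceMatrix(list(zframe.index), D)


@dataclass(frozen=True)
class Merge:
    left: int
    right: int
    height: float
    size: int


@dataclass
class MergeTree:
    """Dendrogram of agglomerative merges (linkage node-id convention)."""

    participant_ids: list[str]
    merges: list[Merge]

    @property
    def n_leaves(self) -> int:
        return len(self.participant_ids)

    @property
    def max_height(self) -> float:
        return self.merges[-1].height if self.merges else 0.0

    def to_linkage_matrix(self) -> np.ndarray:
        """scipy-compatible (n-1, 4) linkage matrix [left, right, height, size]."""
        return np.array(
            [[m.left, m.right, m.height, m.size] for m in self.merges], dtype=float
        )

    def leaf_sets(self) -> dict[int, frozenset[int]]:
        """Leaf-index set under every node id."""
        sets: dict[int, frozenset[int]] = {
            i: frozenset([i]) for i in range(self.n_leaves)
        }
        for k, m in enumerate(self.merges):
            sets[self.n_leaves + k] = sets[m.left] | sets[m.right]
        return sets

    def to_newick(self) -> str:
        """Newick string with branch lengths (height difference to the parent)."""
        heights = {i: 0.0 for i in range(self.n_leaves)}
        for k, m in enumerate(self.merges):
            heights[self.n_leaves + k] = m.height
        labels = {i: pid for i, pid in enumerate(self.participant_ids)}

        def render(node: int, parent_height: float) -> str:
            length = parent_height - heights[node]
            if node < self.n_leaves:
                return f"{labels[node]}:{length:g}"
            m = self.merges[node - self.n_leaves]
            inner = f"({render(m.left, heights[node])},{render(m.right, heights[node])})"
            return f"{inner}:{length:g}"

        if not self.merges:
            return f"{self.participant_ids[0]};" if self.participant_ids else ";"
        root = self.n_leaves + len(self.merges) - 1
        m = self.merges[-1]
        return (
            f"({render(m.left, heights[root])},{render(m.right, heights[root])});"
        )

    def to_merge_json(self) -> list[dict]:
        return [
            {"left": m.left, "right": m.right, "height": m.height, "size": m.size}
            for m in self.merges
        ]


def agglomerate_average(distances: DistanceMatrix) -> MergeTree:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    Repeatedly merges the pair of active clusters with the minimal mean
    pairwise inter-cluster distance; the recorded height is that mean.  Ties
    are broken by the smallest (node-id, node-id) pair, so the merge sequence
    is fully deterministic.
    """
    D = distances.values
    n = distances.n
    if n < 2:
        raise DataError("need at least 2 participants to agglomerate")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = sorted(members)
    # Mean inter-cluster distances. Computed with math.fsum (correctly
    # rounded), so heights do not depend on member iteration order.
    avg: dict[tuple[int, int], float] = {}
    for a in range(n):
        for b in range(a + 1, n):
            avg[(a, b)] = float(D[a, b])

    def cross_average(xs: list[int], ys: list[int]) -> float:
        return math.fsum(D[i, j] for i in xs for j in ys) / (len(xs) * len(ys))

    merges: list[Merge] = []
    next_id = n
    while len(active) > 1:
        best: tuple[int, int] | None = None
        best_d = np.inf
        for ia, a in enumerate(active):
            for b in active[ia + 1 :]:
                d = avg[(a, b)]
                if d < best_d or (d == best_d and best is not None and (a, b) < best):
                    best_d, best = d, (a, b)
        a, b = best  # type: ignore[misc]
        merged = members[a] + members[b]
        merges.append(Merge(a, b, best_d, len(merged)))
        active = [c for c in active if c not in (a, b)]
        for c in active:
            avg[(c, next_id)] = cross_average(merged, members[c])
        members[next_id] = merged
        active.append(next_id)
        next_id += 1
    return MergeTree(distances.participant_ids, merges)


@dataclass
class FlatClustering:
    """A dendrogram cut: labels, sizes, proportions and outlier flags.

    Cluster ids are assigned by decreasing size (cluster 0 = largest); ties
    broken by the smallest member leaf index.
    """

    labels: dict[str, int]
    threshold_used: float
    min_cluster_size: int = 3
    sizes: dict[int, int] = field(init=False)
    proportions: dict[int, float] = field(init=False)
    outlier_flags: dict[int, bool] = field(init=False)

    def __post_init__(self) -> None:
        sizes: dict[int, int] = {}
        for cid in self.labels.values():
            sizes[cid] = sizes.get(cid, 0) + 1
        n = len(self.labels)
        self.sizes = dict(sorted(sizes.items()))
        self.proportions = {cid: s / n for cid, s in self.sizes.items()}
        self.outlier_flags = {cid: s < self.min_cluster_size for cid, s in self.sizes.items()}

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def members(self, cluster_id: int) -> list[str]:
        if cluster_id not in self.sizes:
            raise DataError(f"unknown cluster id {cluster_id}")
        return [pid for pid, cid in self.labels.items() if cid == cluster_id]

    def non_outlier_clusters(self) -> list[int]:
        return [cid for cid, flag in self.outlier_flags.items() if not flag]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": list(self.labels),
                "cluster": [self.labels[p] for p in self.labels],
                "outlier_flag": [
                    self.outlier_flags[self.labels[p]] for p in self.labels
                ],
            }
        )


def cut(
    tree: MergeTree,
    threshold: float,
    mode: str = "fraction",
    min_cluster_size: int = 3,
) -> FlatClustering:
    """Cut the dendrogram at a dissimilarity threshold.

    ``mode="fraction"`` (default) interprets the threshold as a fraction in
    (0, 1] of the maximum merge height; ``mode="absolute"`` uses it on the
    raw height scale.  Merges with height <= cut height are applied; the
    connected leaf sets below the cut are the flat clusters.
    """
    if mode not in ("fraction", "absolute"):
        raise ConfigError(f"unknown cut mode {mode!r}; use 'fraction' or 'absolute'")
    if mode == "fraction":
        if not 0 < threshold <= 1:
            raise ConfigError(f"fraction-mode threshold must be in (0, 1], got {threshold}")
        cut_height = threshold * tree.max_height
    else:
        if threshold <= 0:
            raise ConfigError(f"absolute threshold must be > 0, got {threshold}")
        cut_height = threshold

    n = tree.n_leaves
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    leaf_sets = tree.leaf_sets()
    for m in tree.merges:
        if m.height <= cut_height:
            ra = find(min(leaf_sets[m.left]))
            rb = find(min(leaf_sets[m.right]))
            parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for leaf in range(n):
        groups.setdefault(find(leaf), []).append(leaf)
    # Cluster 0 = largest; ties by smallest member index.
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    labels = {
        tree.participant_ids[leaf]: cid
        for cid, group in enumerate(ordered)
        for leaf in group
    }
    return FlatClustering(labels, threshold_used=cut_height, min_cluster_size=min_cluster_size)


def cluster_profiles(
    clustering: FlatClustering,
    zframe: pd.DataFrame,
    dimensions,
    variable_specs,
) -> pd.DataFrame:
    """Per-cluster mean standardized value, restricted to selected dimensions.

    This is the radar-chart data: one row per cluster, one column per variable
    of the selected dimensions.
    """
    dimensions = list(dimensions)
    if not dimensions:
        raise DataError("cluster_profiles: empty dimension selection")
    variables = [
        var
        for var in zframe.columns
        if var in variable_specs and variable_specs[var].dimension in dimensions
    ]
    if not variables:
        raise DataError(f"no standardized variables for dimensions {dimensions}")
    rows = {}
    for cid in clustering.sizes:
        members = clustering.members(cid)
        rows[cid] = zframe.loc[members, variables].mean(axis=0, skipna=True)
    return pd.DataFrame.from_dict(rows, orient="index")[variables]
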