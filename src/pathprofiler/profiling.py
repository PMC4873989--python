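"""Panel normalization and hierarchical clustering of activity profiles.

The database is standardized per assay (Z-scoring across compounds) and then
clustered with Ward's minimum-variance agglomerative method on Euclidean
distances.  Compounds that act through the same target tend to share an
activity signature across the panel, so they co-cluster even when they are
structurally unrelated.

Ward's method is implemented with the Lance–Williams recurrence on *squared*
Euclidean distances, with merge heights reported on the distance scale (the
same convention as ``scipy.cluster.hierarchy.linkage(method="ward")``).  Two
"Ward" conventions circulate; this one satisfies: the height of merging two
singletons equals their Euclidean distance, and in general

    d²(A, B) = 2·|A||B| / (|A|+|B|) · ||μ_A − μ_B||².

Ties in the merge objective are broken by the lexicographically smallest
cluster-id pair (original rows are ids 0..n−1, merged clusters get ids n,
n+1, ... in merge order), which makes the tree deterministic but — for exact
ties only — dependent on row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import ActivityMatrix, ValidationError


@dataclass
class ClusterResult:
    """Agglomerative merge list plus optional flat cluster labels.

    ``merges`` has one row per merge: (left_id, right_id, height, size),
    with left_id < right_id; heights are Euclidean-scale Ward heights and
    are non-decreasing along the merge order.
    """

    merges: list[tuple[int, int, float, int]]
    compound_ids: list[str]
    flat_labels: dict[str, int] | None = None
    method: str = "ward"
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        n = len(self.compound_ids)
        if len(self.merges) != max(n - 1, 0):
            raise ValidationError(
                f"{n} rows require {n - 1} merges, got {len(self.merges)}"
            )
        heights = [m[2] for m in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValidationError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.compound_ids)

    def to_linkage(self) -> np.ndarray:
        """Merge list as a scipy-style (n-1, 4) linkage array."""
        return np.asarray(self.merges, dtype=float)


def zscore_normalize(matrix: ActivityMatrix) -> ActivityMatrix:
    """Standardize each assay column to mean 0, population sd 1.

    Zero-variance columns (an assay in which no compound showed differential
    activity) are mapped to all-zeros and flagged in
    ``normalization_params["zero_variance"]`` instead of raising, so an
    uninformative assay cannot abort the pipeline.
    """
    if matrix.normalized:
        raise ValidationError("matrix is already normalized")
    if matrix.shape[0] < 2:
        raise ValidationError(
            "Z-scoring needs at least 2 compounds (sd undefined for 1 row)"
        )
    X = matrix.values.to_numpy(float)
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)  # population sd (ddof=0)
    zero_var = sigma == 0.0
    safe_sigma = np.where(zero_var, 1.0, sigma)
    Z = (X - mu) / safe_sigma
    Z[:, zero_var] = 0.0
    params = pd.DataFrame(
        {"mean": mu, "sd": sigma, "zero_variance": zero_var},
        index=matrix.values.columns,
    )
    values = pd.DataFrame(Z, index=matrix.values.index,
                          columns=matrix.values.columns)
    return ActivityMatrix(values, assays=matrix.assays, normalized=True,
                          normalization_params=params)


def ward_cluster(matrix: ActivityMatrix) -> ClusterResult:
    """Ward agglomerative clustering of compounds on Euclidean distance.

    Expects a normalized matrix (raises otherwise, because mixing assays on
    raw percent scales makes Euclidean distance meaningless across readouts
    with different dynamic ranges).
    """
    if not matrix.normalized:
        raise ValidationError("ward_cluster expects a Z-scored matrix")
    X = matrix.values.to_numpy(float)
    n = X.shape[0]
    if n < 2:
        raise ValidationError("clustering needs at least 2 compounds")

    # squared Euclidean distances; Lance-Williams operates on this scale
    D2 = squareform(pdist(X, metric="sqeuclidean"))
    np.fill_diagonal(D2, np.inf)
    active = list(range(n))            # positions into D2 currently in use
    cluster_id = {p: p for p in active}
    size = {p: 1 for p in active}
    next_id = n
    merges: list[tuple[int, int, float, int]] = []

    for _ in range(n - 1):
        sub = D2[np.ix_(active, active)]
        best = np.min(sub)
        # tie-break: smallest (id_a, id_b) pair among minimal-distance pairs
        candidates = []
        rows, cols = np.nonzero(sub == best)
        for r, c in zip(rows, cols):
            if r < c:
                pa, pb = active[r], active[c]
                ia, ib = cluster_id[pa], cluster_id[pb]
                candidates.append((min(ia, ib), max(ia, ib), pa, pb))
        ia, ib, pa, pb = min(candidates)
        na, nb = size[pa], size[pb]
        height = float(np.sqrt(best))
        merges.append((ia, ib, height, na + nb))

        # Lance-Williams update for Ward: write merged cluster into pa
        for pc in active:
            if pc in (pa, pb):
                continue
            nc = size[pc]
            d2 = ((na + nc) * D2[pa, pc] + (nb + nc) * D2[pb, pc]
                  - nc * best) / (na + nb + nc)
            D2[pa, pc] = D2[pc, pa] = d2
        active.remove(pb)
        size[pa] = na + nb
        cluster_id[pa] = next_id
        next_id += 1

    return ClusterResult(merges=merges, compound_ids=matrix.compound_ids)


def cut_tree(result: ClusterResult, k: int) -> dict[str, int]:
    """Flat labels from cutting the merge list to exactly k clusters.

    Applies the first n − k merges; labels are 0..k−1, numbered by first
    appearance in row order (deterministic).
    """
    n = result.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for step, (left, right, _h, _s) in enumerate(result.merges[: n - k]):
        new = n + step
        parent[find(left)] = new
        parent[find(right)] = new

    roots: dict[int, int] = {}
    labels: dict[str, int] = {}
    for leaf, cid in enumerate(result.compound_ids):
        root = find(leaf)
        if root not in roots:
            roots[root] = len(roots)
        labels[cid] = roots[root]
    return labels


def adjusted_rand_index(labels_a: dict[str, int] | pd.Series,
                        labels_b: dict[str, int] | pd.Series) -> float:
    """Chance-adjusted Rand agreement between two compound partitions.

    Both labelings must cover exactly the same compound set; values near 0
    indicate chance-level agreement, 1 is identity up to relabeling.
    """
    from sklearn.metrics import adjusted_rand_score

    a = dict(labels_a)
    b = dict(labels_b)
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))[:5]
        only_b = sorted(set(b) - set(a))[:5]
        raise ValidationError(
            f"labelings cover different compounds (e.g. {only_a} vs {only_b})"
        )
    keys = sorted(a)
    return float(adjusted_rand_score([a[k] for k in keys],
                                     [b[k] for k in keys]))
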