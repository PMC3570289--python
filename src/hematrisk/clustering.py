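"""Agglomerative hierarchical clustering with Canberra distance and
McQuitty (WPGMA) linkage.

This is the engine behind both patient clustering (rows of the biomarker
matrix) and biomarker clustering (columns). The Canberra distance
normalises each coordinate by its magnitude, which suits biomarker panels
whose columns live on wildly different scales, so no prior
standardisation is applied. After merging clusters i and j, WPGMA sets the
distance of the merged cluster to any other cluster m to
(d(i,m) + d(j,m)) / 2; merge heights are therefore non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ConfigError, DegenerateInputError, DimensionError, ParameterError
from .matrix import BiomarkerMatrix


def canberra_distance(x, y) -> float:
    """Canberra distance sum_i |x_i - y_i| / (|x_i| + |y_i|).

    Coordinates where both entries are zero contribute 0 (the 0/0
    convention), which matters for LOD/2-coded biomarker data where many
    small identical values occur.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DimensionError(f"length mismatch: {x.shape} vs {y.shape}")
    num = np.abs(x - y)
    den = np.abs(x) + np.abs(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0, num / den, 0.0)
    return float(terms.sum())


@dataclass
class Dendrogram:
    """A merge tree: scipy linkage matrix plus the leaf identifiers.

    ``linkage`` has the standard (n-1) x 4 layout: merged node indices,
    merge height, merged cluster size. Heights are non-decreasing (WPGMA
    monotonicity), which is validated on construction.
    """

    linkage: np.ndarray
    leaf_ids: pd.Index

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 4):
            raise ConfigError("linkage matrix must have n_leaves - 1 merges")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ConfigError("merge heights decrease: linkage is not WPGMA-monotone")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list:
        """Leaf ids in dendrogram display order."""
        return [self.leaf_ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["left", "right", "height", "size"]
        ).astype({"left": int, "right": int, "size": int})


@dataclass
class ClusterAssignment:
    """Flat k-cluster labelling of the dendrogram leaves (labels 1..k)."""

    labels: pd.Series
    k: int

    def __post_init__(self) -> None:
        observed = set(self.labels.unique())
        if observed != set(range(1, self.k + 1)):
            raise ConfigError(f"expected exactly {self.k} non-empty clusters, got {sorted(observed)}")

    def members(self, label: int) -> pd.Index:
        return self.labels.index[self.labels == label]

    def partition(self) -> set[frozenset]:
        """The assignment as a set of frozensets (order-free comparison)."""
        return {frozenset(self.members(lab)) for lab in range(1, self.k + 1)}


def _extract(matrix, axis: str) -> tuple[np.ndarray, pd.Index]:
    if isinstance(matrix, BiomarkerMatrix):
        df = matrix.values
    elif isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        df = pd.DataFrame(np.asarray(matrix, dtype=float))
    if axis in ("rows", "patients"):
        return df.to_numpy(dtype=float), df.index
    if axis in ("columns", "cols", "biomarkers"):
        return df.to_numpy(dtype=float).T, df.columns
    raise ParameterError(f"axis must be 'rows' or 'columns', got {axis!r}")


def agglomerate(matrix, axis: str = "rows") -> Dendrogram:
    """Hierarchical clustering of matrix rows or columns.

    Canberra distances between item profiles, WPGMA/McQuitty linkage. At
    each step the globally closest pair of clusters is merged.
    """
    data, ids = _extract(matrix, axis)
    if data.shape[0] < 2:
        raise DegenerateInputError("need at least 2 items to cluster")
    dists = pdist(data, metric="canberra")
    linkage = hierarchy.linkage(dists, method="weighted")
    return Dendrogram(linkage=linkage, leaf_ids=pd.Index(ids))


def cut_tree(dendrogram: Dendrogram, k: int) -> ClusterAssignment:
    """Flat k-cluster assignment by undoing the last k-1 merges.

    Labels are integers 1..k assigned in dendrogram leaf order: the
    cluster containing the first displayed leaf is 1, and so on.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    raw = hierarchy.cut_tree(dendrogram.linkage, n_clusters=k).ravel()
    # relabel by first occurrence along the dendrogram leaf ordering
    order = hierarchy.leaves_list(dendrogram.linkage)
    relabel: dict[int, int] = {}
    for leaf in order:
        if raw[leaf] not in relabel:
            relabel[raw[leaf]] = len(relabel) + 1
    labels = pd.Series(
        [relabel[v] for v in raw], index=dendrogram.leaf_ids, name="cluster"
    )
    return ClusterAssignment(labels=labels, k=k)


@dataclass
class BootstrapResult:
    """Per-repetition agreement scores plus a co-clustering consensus matrix."""

    scores: np.ndarray
    consensus: pd.DataFrame
    k: int
    n_boot: int


def bootstrap_stability(
    matrix, k: int, n_boot: int = 100, seed: int = 0, axis: str = "rows"
) -> BootstrapResult:
    """Cluster-stability assessment by bootstrap resampling of patients.

    Each repetition resamples the items with replacement (n-out-of-n),
    collapses duplicates, reclusters the unique sampled items, cuts at k,
    and scores agreement with the full-data assignment (restricted to the
    sampled items) by the adjusted Rand index. Also accumulates a pairwise
    co-clustering consensus matrix over repetitions.
    """
    from sklearn.metrics import adjusted_rand_score

    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    data, ids = _extract(matrix, axis)
    n = data.shape[0]
    full = cut_tree(agglomerate(pd.DataFrame(data, index=ids), "rows"), k)
    full_labels = full.labels.to_numpy()

    rng = np.random.default_rng(seed)
    scores = np.full(n_boot, np.nan)
    co = np.zeros((n, n))
    seen = np.zeros((n, n))
    for b in range(n_boot):
        sampled = rng.integers(0, n, size=n)
        uniq = np.unique(sampled)
        if uniq.size < max(2, k):
            continue
        sub = data[uniq]
        assign = cut_tree(agglomerate(pd.DataFrame(sub), "rows"), k)
        sub_labels = assign.labels.to_numpy()
        scores[b] = adjusted_rand_score(full_labels[uniq], sub_labels)
        same = sub_labels[:, None] == sub_labels[None, :]
        co[np.ix_(uniq, uniq)] += same
        seen[np.ix_(uniq, uniq)] += 1
    with np.errstate(invalid="ignore"):
        consensus = np.where(seen > 0, co / seen, np.nan)
    return BootstrapResult(
        scores=scores,
        consensus=pd.DataFrame(consensus, index=ids, columns=ids),
        k=k,
        n_boot=n_boot,
    )
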