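"""UPGMA clustering, cophenetic validation, heat-map ordering and PCA.

UPGMA (unweighted pair-group method with arithmetic averages) repeatedly
merges the two closest clusters; the distance from a merged cluster to any
other is the size-weighted mean of its members' distances, so merge heights
are non-decreasing and the tree is ultrametric.  Tree quality against the
original distances is measured by the cophenetic correlation: the Pearson
correlation between the input pairwise distances and the height of each
pair's first common merge.

The heat-map pipeline averages parameters within (land-use, season) groups,
min-max normalizes each parameter to [0, 1] so incommensurate units become
comparable, and clusters groups on Bray-Curtis distances.  PCA is computed by
singular value decomposition of column-centered (optionally standardized)
data, with a deterministic sign convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .fingerprint import bray_curtis, dice_similarity, jaccard_similarity
from .synthetic import StudyDesign

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "PCAResult",
    "distance_matrix",
    "upgma",
    "cophenetic_distances",
    "cophenetic_correlation",
    "cut_tree",
    "minmax_normalize",
    "group_average",
    "pca",
    "to_newick",
]

METRICS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "bray_curtis": bray_curtis,
    "dice_dissimilarity": lambda a, b: 1.0 - dice_similarity(a, b),
    "jaccard_dissimilarity": lambda a, b: 1.0 - jaccard_similarity(a, b),
    "euclidean": lambda a, b: float(np.linalg.norm(np.asarray(a) - np.asarray(b))),
}


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape must match labels")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly zero")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.isnan(v).any():
            raise ValueError("NaN distances are not allowed")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class Merge:
    """One agglomeration step; node ids follow the scipy convention
    (leaves 0..n-1, the i-th merge creates node n+i)."""

    left: int
    right: int
    distance: float
    size: int


@dataclass(frozen=True)
class Dendrogram:
    leaf_labels: tuple[str, ...]
    merges: tuple[Merge, ...]

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        if len(self.merges) != n - 1:
            raise ValueError("a dendrogram over n leaves has exactly n-1 merges")
        heights = [m.distance for m in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)


@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # variables x components (orthonormal columns)
    variance_percent: np.ndarray
    standardized: bool


def distance_matrix(
    rows: np.ndarray,
    labels: Sequence[str],
    metric: str = "bray_curtis",
) -> DistanceMatrix:
    """Pairwise distances between profile rows under the named metric."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    rows = np.asarray(rows, dtype=float)
    if rows.shape[0] < 2:
        raise ValueError("need at least two rows")
    fn = METRICS[metric]
    n = rows.shape[0]
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = fn(rows[i], rows[j])
    return DistanceMatrix(labels=tuple(labels), values=d)


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration with a deterministic tie rule.

    At each step the pair of clusters at minimal distance is merged; among
    exactly tied pairs the lexicographically smallest pair of cluster leaf
    sets wins.  The merged cluster's distance to any other cluster is the
    size-weighted arithmetic mean of the members' distances.
    """
    n = d.n
    if n < 2:
        raise ValueError("need at least two leaves")
    dist = {
        (i, j): float(d.values[i, j]) for i, j in combinations(range(n), 2)
    }
    active: dict[int, tuple[int, tuple[int, ...]]] = {
        i: (1, (i,)) for i in range(n)
    }  # node id -> (size, sorted leaf ids)
    merges: list[Merge] = []
    next_id = n

    def key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    while len(active) > 1:
        best = None
        best_pair = None
        for (i, j), v in dist.items():
            tie_key = (v, active[i][1], active[j][1])
            if best is None or tie_key < best:
                best = tie_key
                best_pair = (i, j)
        i, j = best_pair  # type: ignore[misc]
        h = dist[(i, j)]
        si, leaves_i = active[i]
        sj, leaves_j = active[j]
        new = next_id
        next_id += 1
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist.pop(key(i, k))
            djk = dist.pop(key(j, k))
            dist[key(new, k)] = (si * dik + sj * djk) / (si + sj)
        dist.pop((i, j))
        del active[i], active[j]
        active[new] = (si + sj, tuple(sorted(leaves_i + leaves_j)))
        merges.append(Merge(left=i, right=j, distance=h, size=si + sj))
    return Dendrogram(leaf_labels=d.labels, merges=tuple(merges))


def _leaf_sets(t: Dendrogram) -> dict[int, set[int]]:
    n = t.n_leaves
    sets: dict[int, set[int]] = {i: {i} for i in range(n)}
    for idx, m in enumerate(t.merges):
        sets[n + idx] = sets[m.left] | sets[m.right]
    return sets


def cophenetic_distances(t: Dendrogram) -> np.ndarray:
    """Pairwise first-common-merge heights; an ultrametric by construction."""
    n = t.n_leaves
    coph = np.zeros((n, n))
    sets = _leaf_sets(t)
    for idx, m in enumerate(t.merges):
        left, right = sets[m.left], sets[m.right]
        for a in left:
            for b in right:
                coph[a, b] = coph[b, a] = m.distance
    return coph


def cophenetic_correlation(t: Dendrogram, d: DistanceMatrix) -> float:
    """Pearson correlation of original vs tree-implied pairwise distances."""
    if tuple(t.leaf_labels) != tuple(d.labels):
        raise ValueError("dendrogram and distance matrix label sets differ")
    n = d.n
    if n < 3:
        raise ValueError("cophenetic correlation needs at least 3 leaves")
    iu = np.triu_indices(n, k=1)
    orig = d.values[iu]
    coph = cophenetic_distances(t)[iu]
    if np.std(orig) == 0 or np.std(coph) == 0:
        # all distances equal: the tree reproduces them exactly
        if np.allclose(orig, coph):
            return 1.0
        raise ValueError("correlation undefined for constant distances")
    r, _ = stats.pearsonr(orig, coph)
    return float(r)


def cut_tree(t: Dendrogram, k: int) -> list[set[str]]:
    """Partition leaves into k clusters by undoing the last k-1 merges."""
    n = t.n_leaves
    if not 1 <= k <= n:
        raise ValueError("k must be between 1 and the number of leaves")
    sets = _leaf_sets(t)
    roots = {n + len(t.merges) - 1}
    while len(roots) < k:
        # replace the highest remaining internal node with its children
        node = max(r for r in roots if r >= n)
        m = t.merges[node - n]
        roots.remove(node)
        roots.update((m.left, m.right))
    return [
        {t.leaf_labels[i] for i in sets[r]}
        for r in sorted(roots)
    ]


def minmax_normalize(table: np.ndarray, axis: int = 1) -> np.ndarray:
    """Scale each parameter (row by default) to [0, 1] via (x-min)/(max-min).

    A constant parameter carries no contrast; it is emitted as all 0.5 with a
    warning rather than dividing by zero.
    """
    x = np.asarray(table, dtype=float)
    mins = x.min(axis=axis, keepdims=True)
    maxs = x.max(axis=axis, keepdims=True)
    span = maxs - mins
    flat = span == 0
    if flat.any():
        warnings.warn("constant parameter(s) min-max normalized to 0.5", stacklevel=2)
    safe = np.where(flat, 1.0, span)
    out = (x - mins) / safe
    return np.where(np.broadcast_to(flat, out.shape), 0.5, out)


def group_average(
    values: Mapping[str, Sequence[float] | float],
    design: StudyDesign,
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Mean per (land_use, season) group; rows follow design group order.

    ``values`` maps sample_id to a scalar or parameter vector.  Returns the
    (groups x parameters) array and the group key list.
    """
    groups = design.groups()
    buckets: dict[tuple[str, str], list[np.ndarray]] = {g: [] for g in groups}
    for s in design.samples:
        if s.sample_id not in values:
            raise ValueError(f"missing values for sample {s.sample_id}")
        buckets[(s.land_use, s.season)].append(
            np.atleast_1d(np.asarray(values[s.sample_id], dtype=float))
        )
    rows = []
    for g in groups:
        if not buckets[g]:
            raise ValueError(f"empty group {g}")
        rows.append(np.mean(buckets[g], axis=0))
    return np.vstack(rows), groups


def pca(table: np.ndarray, standardize: bool = True) -> PCAResult:
    """Principal component analysis by SVD of centered (scaled) data.

    With ``standardize`` the correlation matrix is decomposed (each variable
    divided by its sample standard deviation) — appropriate when variables
    carry incommensurate units.  Component signs are fixed so the
    largest-magnitude loading of each component is positive.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 variables")
    if np.isnan(x).any():
        raise ValueError("missing values are not supported (no imputation)")
    centered = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant variable cannot be standardized")
        centered = centered / sd
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    loadings = vt.T
    # deterministic orientation
    for c in range(loadings.shape[1]):
        col = loadings[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, c] = -col
            u[:, c] = -u[:, c]
    scores = u * s
    eig = s**2 / (x.shape[0] - 1)
    total = eig.sum()
    variance_percent = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_percent=variance_percent,
        standardized=standardize,
    )


def to_newick(t: Dendrogram) -> str:
    """Newick serialization with the ultrametric height convention h = d/2.

    Each node sits at half its merge distance, leaves at height 0, and branch
    lengths are parent height minus child height — so the tree path between
    two leaves equals their cophenetic distance.
    """
    n = t.n_leaves
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for idx, m in enumerate(t.merges):
        node = n + idx
        height[node] = m.distance / 2.0
        children[node] = (m.left, m.right)

    def render(node: int, parent_height: float) -> str:
        blen = parent_height - height[node]
        if node < n:
            return f"{t.leaf_labels[node]}:{blen:.10g}"
        l, r = children[node]
        h = height[node]
        return f"({render(l, h)},{render(r, h)}):{blen:.10g}"

    root = n + len(t.merges) - 1
    l, r = children[root]
    h = height[root]
    return f"({render(l, h)},{render(r, h)});"
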