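"""Movement-bout comparison by DTW / dynamic time alignment kernels, and
hierarchical clustering of the resulting distance matrix.

Two dissimilarities between bouts (short multivariate time series -- 3D
reach trajectories or 1-D angle curves) are provided:

* **DTW**: classic dynamic programming with Euclidean local cost and the
  symmetric step set {(1,0), (0,1), (1,1)}; the reported dissimilarity is
  the accumulated cost divided by the alignment path length, so bouts of
  different durations stay comparable.

* **DTAK**: a dynamic time alignment kernel. Local similarity is Gaussian,
  k(x_i, y_j) = exp(-||x_i - y_j||^2 / (2 sigma^2)); similarities are
  accumulated along a warping path with the max-rule recursion (diagonal
  steps weighted 2), normalized by n + m, and finally self-normalized
  K^(x,y) = K(x,y)/sqrt(K(x,x) K(y,y)) so that K^(x,x) = 1. The
  kernel-induced distance sqrt(2 - 2 K^) turns it into a dissimilarity.

The pairwise matrix feeds standard agglomerative clustering
(scipy.cluster.hierarchy); by default multidimensional bouts are compared
after subtracting each bout's starting point, so clusters reflect movement
shape rather than absolute location.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, squareform

__all__ = [
    "Bout",
    "AlignmentResult",
    "SeriesDistanceMatrix",
    "Dendrogram",
    "dtw_align",
    "dtak_kernel",
    "kernel_distance",
    "median_heuristic_sigma",
    "distance_matrix",
    "hierarchical_cluster",
]


@dataclass
class Bout:
    """One movement bout: an ordered (n, d) series of samples at known fps."""

    id: str
    series: np.ndarray
    fps: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.series, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        self.series = arr
        if len(arr) < 2:
            raise ValueError(f"bout {self.id!r}: need at least 2 samples")
        if np.isnan(arr).any():
            raise ValueError(
                f"bout {self.id!r} contains gaps; interpolate upstream "
                "(kinematics.interpolate_gaps) before clustering")

    @property
    def dim(self) -> int:
        return self.series.shape[1]


@dataclass
class AlignmentResult:
    cost: float
    path: list[tuple[int, int]]
    normalized_cost: float


@dataclass
class SeriesDistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    method: str  # "dtw" | "dtak"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal must be zero")
        if (m < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(path)


@dataclass
class Dendrogram:
    """Agglomerative merge history (scipy linkage convention)."""

    ids: list[str]
    linkage_matrix: np.ndarray  # (n-1, 4): cluster i, cluster j, height, size
    linkage: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int | None = None, height: float | None = None) -> np.ndarray:
        """Flat cluster assignments (0-based) at k clusters or a merge height."""
        if (k is None) == (height is None):
            raise ValueError("specify exactly one of k or height")
        if k is not None:
            if k > len(self.ids):
                raise ValueError(f"k={k} exceeds the number of bouts ({len(self.ids)})")
            labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        else:
            labels = hierarchy.fcluster(self.linkage_matrix, t=height, criterion="distance")
        return labels - 1

    def to_newick(self) -> str:
        """Nested-parenthesis rendering with merge heights as branch lengths."""
        n = len(self.ids)
        nodes: dict[int, tuple[str, float]] = {i: (self.ids[i], 0.0) for i in range(n)}
        for m, (i, j, h, _) in enumerate(self.linkage_matrix):
            li, hi = nodes[int(i)]
            lj, hj = nodes[int(j)]
            rep = f"({li}:{h - hi:.6g},{lj}:{h - hj:.6g})"
            nodes[n + m] = (rep, float(h))
        return nodes[n + len(self.linkage_matrix) - 1][0] + ";"

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.linkage_matrix,
                            columns=["cluster_i", "cluster_j", "height", "size"])


# ---------------------------------------------------------------------------
# DTW

def dtw_align(x: Bout, y: Bout) -> AlignmentResult:
    """Dynamic time warping with Euclidean local cost and symmetric steps.

    D(i,j) = c(x_i, y_j) + min(D(i-1,j), D(i,j-1), D(i-1,j-1)); the path is
    recovered by backtracking with a deterministic tie-break preferring the
    diagonal, then (i-1,j), then (i,j-1). ``normalized_cost`` divides the
    accumulated cost by the path length.
    """
    if x.dim != y.dim:
        raise ValueError(f"dimension mismatch: {x.dim} vs {y.dim}")
    c = cdist(x.series, y.series)
    n, m = c.shape
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        row = c[i - 1]
        for j in range(1, m + 1):
            D[i, j] = row[j - 1] + min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    # backtrack
    path = [(n - 1, m - 1)]
    i, j = n, m
    while (i, j) != (1, 1):
        candidates = []
        if i > 1 and j > 1:
            candidates.append((D[i - 1, j - 1], 0, (i - 1, j - 1)))
        if i > 1:
            candidates.append((D[i - 1, j], 1, (i - 1, j)))
        if j > 1:
            candidates.append((D[i, j - 1], 2, (i, j - 1)))
        _, _, (i, j) = min(candidates, key=lambda t: (t[0], t[1]))
        path.append((i - 1, j - 1))
    path.reverse()
    cost = float(D[n, m])
    return AlignmentResult(cost=cost, path=path, normalized_cost=cost / len(path))


# ---------------------------------------------------------------------------
# DTAK

def _dtak_raw(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Unnormalized alignment-kernel score, scaled by path-weight total n+m."""
    sq = cdist(x, y, metric="sqeuclidean")
    k = np.exp(-sq / (2.0 * sigma**2))
    n, m = k.shape
    K = np.full((n, m), -np.inf)
    K[0, 0] = 2.0 * k[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = -np.inf
            if i > 0 and j > 0:
                best = K[i - 1, j - 1] + 2.0 * k[i, j]
            if i > 0:
                best = max(best, K[i - 1, j] + k[i, j])
            if j > 0:
                best = max(best, K[i, j - 1] + k[i, j])
            K[i, j] = best
    return float(K[n - 1, m - 1] / (n + m))


def dtak_kernel(x: Bout, y: Bout, sigma: float) -> float:
    """Normalized dynamic time alignment kernel K^(x, y) in (0, 1].

    Gaussian local similarity, max-rule accumulation with diagonal weight 2,
    path-length normalization by n + m, then self-normalization
    K^ = K/sqrt(K(x,x) K(y,y)) so K^(x, x) = 1 exactly.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if x.dim != y.dim:
        raise ValueError(f"dimension mismatch: {x.dim} vs {y.dim}")
    kxy = _dtak_raw(x.series, y.series, sigma)
    kxx = _dtak_raw(x.series, x.series, sigma)
    kyy = _dtak_raw(y.series, y.series, sigma)
    return float(kxy / np.sqrt(kxx * kyy))


def kernel_distance(x: Bout, y: Bout, sigma: float) -> float:
    """Kernel-induced (feature-space) distance sqrt(2 - 2 K^(x, y)) >= 0."""
    return float(np.sqrt(max(0.0, 2.0 - 2.0 * dtak_kernel(x, y, sigma))))


def median_heuristic_sigma(bouts: list[Bout]) -> float:
    """Median pairwise sample distance across all bouts (the median heuristic)."""
    samples = np.concatenate([b.series for b in bouts], axis=0)
    if len(samples) > 500:  # subsample for the quantile only
        idx = np.linspace(0, len(samples) - 1, 500).astype(int)
        samples = samples[idx]
    d = cdist(samples, samples)
    vals = d[np.triu_indices_from(d, k=1)]
    med = float(np.median(vals))
    return med if med > 0 else 1.0


# ---------------------------------------------------------------------------

def _centered(bouts: list[Bout], center: str) -> list[Bout]:
    if center == "none":
        return bouts
    if center == "start":
        return [Bout(b.id, b.series - b.series[0], b.fps) for b in bouts]
    raise ValueError(f"unknown centering {center!r}")


def distance_matrix(bouts: list[Bout], method: str = "dtw", sigma: float | None = None,
                    center: str | None = None) -> SeriesDistanceMatrix:
    """All-pairs bout dissimilarity (computed once per unordered pair).

    ``method="dtw"`` uses the path-normalized DTW cost; ``method="dtak"``
    the kernel-induced distance with Gaussian width ``sigma`` (default:
    median heuristic). ``center="start"`` (the default for d >= 2)
    subtracts each bout's first sample so clustering reflects shape, not
    location; ``center="none"`` compares raw values.
    """
    if len(bouts) < 2:
        raise ValueError("need at least 2 bouts")
    dims = {b.dim for b in bouts}
    if len(dims) != 1:
        raise ValueError(f"bouts have mixed dimensions: {sorted(dims)}")
    if method not in ("dtw", "dtak"):
        raise ValueError(f"unknown method {method!r}")
    if center is None:
        center = "start" if dims.pop() > 1 else "none"
    work = _centered(bouts, center)
    if method == "dtak" and sigma is None:
        sigma = median_heuristic_sigma(work)
    n = len(work)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if method == "dtw":
                d = dtw_align(work[i], work[j]).normalized_cost
            else:
                d = kernel_distance(work[i], work[j], sigma)
            m[i, j] = m[j, i] = d
    params = {"center": center}
    if method == "dtak":
        params["sigma"] = sigma
    return SeriesDistanceMatrix(ids=[b.id for b in bouts], matrix=m,
                                method=method, params=params)


def hierarchical_cluster(m: SeriesDistanceMatrix, linkage: str = "average",
                         k: int | None = None,
                         height: float | None = None) -> tuple[Dendrogram, np.ndarray | None]:
    """Agglomerative clustering of a bout distance matrix.

    ``linkage`` is one of single/complete/average (Lance-Williams updates
    via scipy). Returns the dendrogram and, when ``k`` or ``height`` is
    given, the flat assignments (else None).
    """
    if linkage not in ("single", "complete", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    condensed = squareform(m.matrix, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    dend = Dendrogram(ids=list(m.ids), linkage_matrix=Z, linkage=linkage)
    assignments = None
    if k is not None or height is not None:
        assignments = dend.cut(k=k, height=height)
    return dend, assignments
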