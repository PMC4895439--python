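"""Silhouette-guided k-means classification of unfolding step lengths.

The measured step lengths from all force conditions are pooled and
classified with replicated k-means++ (Euclidean distance, best of
``n_replicas`` initialisations by within-cluster sum of squares) for every
candidate cluster count k; the selected solution maximises the mean
silhouette over the whole data set, breaking ties by the fewest negative
per-point silhouettes and then by the smallest k.

For point i with mean intra-cluster dissimilarity a(i) and mean
dissimilarity b(i) to the nearest other cluster,

    s(i) = (b(i) - a(i)) / max(a(i), b(i)),      -1 <= s(i) <= 1.

Points in singleton clusters get s(i) = 0 (common convention).  Cluster
quality is inspected by reconstructing per-condition cumulative length
histograms as Gaussian mixtures with cluster means/SDs and subset occupancy
weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.cluster import KMeans

__all__ = [
    "ClusterSolution",
    "kmeans",
    "silhouette",
    "select_k",
    "reconstruct_histogram",
]


@dataclass
class ClusterSolution:
    """A fitted k-means solution over 1-D step lengths (nm).

    Clusters are relabelled in ascending centroid order, so label ``c``
    carries the conventional name ``C{c+1}``.
    """

    k: int
    centroids: np.ndarray  # nm, ascending
    assignments: np.ndarray  # int label per point
    inertia: float  # within-cluster sum of squares
    data: np.ndarray  # the fitted 1-D lengths
    a: np.ndarray  # mean intra-cluster dissimilarity per point
    b: np.ndarray  # mean dissimilarity to the nearest other cluster
    s: np.ndarray  # silhouette per point

    @property
    def mean_silhouette(self) -> float:
        return float(np.mean(self.s))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.s < 0))

    def predict(self, x) -> np.ndarray:
        """Nearest-centroid labels for new lengths."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.argmin(np.abs(x[:, None] - self.centroids[None, :]), axis=1)

    def cluster_table(self) -> pd.DataFrame:
        """Per-cluster summary: name, mean (nm), sd (nm), n."""
        rows = []
        for c in range(self.k):
            pts = self.data[self.assignments == c]
            rows.append(
                {
                    "cluster": f"C{c + 1}",
                    "mean_nm": float(pts.mean()),
                    "sd_nm": float(pts.std(ddof=1)) if pts.size > 1 else 0.0,
                    "n": int(pts.size),
                }
            )
        return pd.DataFrame(rows)


def silhouette(data, assignments, return_components: bool = False):
    """Per-point silhouette s(i) of a 1-D clustering (direct a/b formula).

    ``a(i)`` averages |x_i - x_j| over the other members of i's cluster;
    ``b(i)`` is the smallest such average over the other clusters.
    Requires at least two non-empty clusters; singleton clusters yield
    s(i) = 0.
    """
    x = np.asarray(data, dtype=float).ravel()
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    dist = np.abs(x[:, None] - x[None, :])
    n = x.size
    a = np.zeros(n)
    b = np.full(n, np.inf)
    for c in uniq:
        mask = labels == c
        size = int(mask.sum())
        sums = dist[:, mask].sum(axis=1)
        a[mask] = sums[mask] / (size - 1) if size > 1 else 0.0
        other = ~mask
        b[other] = np.minimum(b[other], sums[other] / size)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (b - a) / np.maximum(a, b)
    s[~np.isfinite(s)] = 0.0
    for c in uniq:  # singleton convention
        mask = labels == c
        if mask.sum() == 1:
            s[mask] = 0.0
            a[mask] = 0.0
    if return_components:
        return s, a, b
    return s


def kmeans(data, k: int, n_replicas: int = 200, seed=None) -> ClusterSolution:
    """Replicated k-means++ on 1-D lengths; best of ``n_replicas`` by WCSS."""
    x = np.asarray(data, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty data")
    n_distinct = np.unique(x).size
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the number of distinct points ({n_distinct})"
        )
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rs = int(ss.generate_state(1)[0] % (2**31 - 1))
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_replicas,
        random_state=rs,
        algorithm="lloyd",
    ).fit(x[:, None])
    # relabel ascending by centroid
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty_like(order)
    relabel[order] = np.arange(k)
    labels = relabel[km.labels_]
    centroids = km.cluster_centers_.ravel()[order]
    if k >= 2:
        s, a, b = silhouette(x, labels, return_components=True)
    else:
        s = a = b = np.zeros(x.size)
    return ClusterSolution(
        k=k,
        centroids=centroids,
        assignments=labels,
        inertia=float(km.inertia_),
        data=x,
        a=a,
        b=b,
        s=s,
    )


def select_k(
    data,
    k_range=range(2, 11),
    n_replicas: int = 20000,
    seed=None,
) -> ClusterSolution:
    """Silhouette model selection over candidate cluster counts.

    Fits replicated k-means for each k in ``k_range`` and returns the
    solution with the highest mean silhouette; ties are broken by the
    fewest negative silhouettes, then by the smaller k.
    """
    x = np.asarray(data, dtype=float).ravel()
    ks = sorted(int(k) for k in k_range)
    if x.size <= max(ks):
        raise ValueError(
            f"need more than max(k_range)={max(ks)} points, got {x.size}"
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child = ss.spawn(len(ks))
    best: ClusterSolution | None = None
    for k, ss in zip(ks, child):
        sol = kmeans(x, k, n_replicas=n_replicas, seed=ss)
        if best is None:
            best = sol
            continue
        key = (-round(sol.mean_silhouette, 12), sol.n_negative, sol.k)
        best_key = (-round(best.mean_silhouette, 12), best.n_negative, best.k)
        if key < best_key:
            best = sol
    assert best is not None
    return best


def reconstruct_histogram(
    solution: ClusterSolution,
    subset=None,
    x=None,
    sigma_floor: float = 0.05,
):
    """Gaussian cumulative-histogram reconstruction of a data subset.

    Returns ``(x, cdf, weights)`` where the model CDF is the mixture
    sum_c w_c * Phi((x - mu_c) / sigma_c): mu_c/sigma_c are the cluster
    mean/SD over the FULL fitted data and the weights are the occupancy of
    each cluster within ``subset`` (default: all fitted data).  Clusters
    represented by fewer than 2 fitted points get ``sigma_floor`` with a
    warning.
    """
    sub = solution.data if subset is None else np.asarray(subset, dtype=float).ravel()
    if sub.size == 0:
        raise ValueError("empty subset")
    labels = solution.predict(sub)
    weights = np.bincount(labels, minlength=solution.k).astype(float)
    weights /= weights.sum()

    mus = np.empty(solution.k)
    sds = np.empty(solution.k)
    for c in range(solution.k):
        pts = solution.data[solution.assignments == c]
        mus[c] = pts.mean() if pts.size else solution.centroids[c]
        if pts.size < 2:
            warnings.warn(
                f"cluster C{c + 1} has <2 points; applying sigma floor "
                f"{sigma_floor} nm",
                stacklevel=2,
            )
            sds[c] = sigma_floor
        else:
            sds[c] = max(float(pts.std(ddof=1)), sigma_floor)
    if x is None:
        lo = float(sub.min() - 3 * sds.max())
        hi = float(sub.max() + 3 * sds.max())
        x = np.linspace(lo, hi, 512)
    x = np.asarray(x, dtype=float)
    cdf = np.zeros_like(x)
    for c in range(solution.k):
        if weights[c] > 0:
            cdf += weights[c] * norm.cdf((x - mus[c]) / sds[c])
    return x, cdf, weights
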