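"""Partitioning of latent spaces and raw structures, plus validity indices.

k-means and Ward agglomerative clustering operate on embeddings or feature
matrices; the GROMOS algorithm clusters raw conformations directly by
pairwise superposed RMSD, greedily growing each cluster around the structure
with the most neighbors within a cutoff.  Partitions are scored with the
silhouette coefficient and the Davies–Bouldin index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from sklearn.cluster import KMeans as _SKKMeans
from sklearn.metrics import davies_bouldin_score as _sk_db
from sklearn.metrics import silhouette_samples as _sk_silhouette_samples

from .dimred import Embedding
from .fingerprints import FeatureMatrix
from .traj import AtomSelection, ConformationSet

__all__ = [
    "ClusterLabels",
    "kmeans",
    "agglomerative_ward",
    "ward_linkage",
    "gromos_cluster",
    "gromos_from_distances",
    "pairwise_rmsd",
    "silhouette",
    "davies_bouldin",
]


@dataclass
class ClusterLabels:
    """A partition of frames into k clusters."""

    labels: np.ndarray
    k: int
    method: str  # KMEANS | WARD | GROMOS
    centers_hint: np.ndarray | None = None  # per-cluster frame index

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        used = np.unique(self.labels)
        if used.min() < 0 or used.max() >= self.k or used.size != self.k:
            raise ValueError("labels must use every value in [0, k)")

    def populations(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def _as_points(points) -> np.ndarray:
    if isinstance(points, Embedding):
        return points.points
    if isinstance(points, FeatureMatrix):
        return points.values
    return np.asarray(points, dtype=float)


def kmeans(points, k: int, seed: int = 0):
    """Seeded k-means++ with Lloyd iterations.

    Returns (ClusterLabels, inertia).  ``k`` may not exceed the number of
    distinct points.
    """
    X = _as_points(points)
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct points")
    model = _SKKMeans(n_clusters=k, init="k-means++", n_init=10,
                      max_iter=300, algorithm="lloyd", random_state=seed)
    raw = model.fit_predict(X)
    labels = _relabel_first_occurrence(raw)
    return ClusterLabels(labels, k, "KMEANS"), float(model.inertia_)


def ward_linkage(points) -> np.ndarray:
    """Scipy linkage matrix for Ward agglomeration (Lance–Williams update)."""
    X = _as_points(points)
    return sch.linkage(X, method="ward")


def agglomerative_ward(points, k: int) -> ClusterLabels:
    """Ward agglomerative clustering cut at k clusters (deterministic)."""
    X = _as_points(points)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n} points")
    if k == n:
        return ClusterLabels(np.arange(n), k, "WARD")
    Z = ward_linkage(X)
    raw = sch.fcluster(Z, t=k, criterion="maxclust")
    labels = _relabel_first_occurrence(raw)
    if labels.max() + 1 != k:
        raise RuntimeError("Ward cut did not produce the requested k")
    return ClusterLabels(labels, k, "WARD")


def _relabel_first_occurrence(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to 0..k−1 in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


# ---------------------------------------------------------------------------
# GROMOS clustering
# ---------------------------------------------------------------------------

def pairwise_rmsd(cset: ConformationSet,
                  selection: AtomSelection | None = None) -> np.ndarray:
    """Symmetric matrix of pairwise Kabsch RMSD (nm) over a selection.

    Each frame pair is optimally superposed (translation + proper rotation);
    the RMSD is evaluated from the singular values of the cross-covariance,
    with the determinant sign correction that forbids reflections.
    """
    selection = selection or AtomSelection.calpha()
    sel = selection.resolve(cset)
    if sel.size == 0:
        raise ValueError("empty atom selection for RMSD")
    X = cset.coords[:, sel, :]
    X = X - X.mean(axis=1, keepdims=True)
    n_sel = sel.size
    ssq = np.einsum("fax,fax->f", X, X)
    F = cset.n_frames
    D = np.zeros((F, F))
    for i in range(F - 1):
        H = np.einsum("ax,fay->fxy", X[i], X[i + 1:])  # cross-covariances
        U, S, Vt = np.linalg.svd(H)
        sign = np.sign(np.linalg.det(np.einsum("fxy,fyz->fxz", U, Vt)))
        trace = S[:, 0] + S[:, 1] + sign * S[:, 2]
        msd = np.maximum(ssq[i] + ssq[i + 1:] - 2.0 * trace, 0.0) / n_sel
        D[i, i + 1:] = D[i + 1:, i] = np.sqrt(msd)
    return D


def gromos_from_distances(D: np.ndarray, cutoff: float) -> ClusterLabels:
    """GROMOS greedy clustering on a precomputed distance matrix.

    Repeatedly pick the pool member with the most neighbors within
    ``cutoff`` (ties broken by lowest index), make it a cluster center, and
    remove it plus its neighbors from the pool.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    remaining = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    centers: list[int] = []
    while remaining.any():
        idx = np.nonzero(remaining)[0]
        sub = D[np.ix_(idx, idx)] <= cutoff
        counts = sub.sum(axis=1) - 1  # exclude self
        center = idx[int(np.argmax(counts))]  # argmax ties -> lowest index
        members = idx[sub[np.nonzero(idx == center)[0][0]]]
        labels[members] = len(centers)
        centers.append(int(center))
        remaining[members] = False
    return ClusterLabels(labels, len(centers), "GROMOS",
                         centers_hint=np.asarray(centers, dtype=int))


def gromos_cluster(cset: ConformationSet, cutoff: float,
                   selection: AtomSelection | None = None) -> ClusterLabels:
    """GROMOS clustering of conformations by pairwise superposed RMSD.

    ``cutoff`` is in nm; the default selection is Cα.  ``centers_hint``
    records the center frame of each cluster in discovery order.
    """
    D = pairwise_rmsd(cset, selection=selection or AtomSelection.calpha())
    return gromos_from_distances(D, cutoff)


# ---------------------------------------------------------------------------
# Validity indices
# ---------------------------------------------------------------------------

def silhouette(points, labels: ClusterLabels,
               precomputed: bool = False):
    """Mean silhouette coefficient and per-point scores.

    s_i = (b_i − a_i)/max(a_i, b_i) with a_i the mean intra-cluster and b_i
    the smallest mean other-cluster distance; points in singleton clusters
    score 0 by convention.  ``precomputed=True`` treats ``points`` as a
    square distance matrix.
    """
    if labels.k < 2:
        raise ValueError("silhouette requires k >= 2")
    X = _as_points(points)
    if labels.k == len(labels.labels):  # all singletons: s_i = 0 by convention
        return 0.0, np.zeros(labels.k)
    metric = "precomputed" if precomputed else "euclidean"
    scores = _sk_silhouette_samples(X, labels.labels, metric=metric)
    return float(scores.mean()), scores


def davies_bouldin(points, labels: ClusterLabels) -> float:
    """Davies–Bouldin index: mean over clusters of max_j (S_i+S_j)/M_ij.

    S is the mean distance of members to their centroid, M the distance
    between centroids; lower is better.  Coincident centroids make the
    index undefined and raise.
    """
    if labels.k < 2:
        raise ValueError("Davies-Bouldin requires k >= 2")
    X = _as_points(points)
    centroids = np.array([X[labels.labels == c].mean(axis=0)
                          for c in range(labels.k)])
    dists = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=2)
    np.fill_diagonal(dists, np.inf)
    if np.any(dists == 0):
        raise ZeroDivisionError("coincident cluster centroids")
    return float(_sk_db(X, labels.labels))
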