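"""Representative-ensemble design: the core protocol of the package.

Given a fingerprint matrix of a trajectory, the protocol

1. embeds the frames with tSNE at each perplexity of a scan grid,
2. partitions each embedding with Ward agglomeration at each ensemble size k,
3. scores every (perplexity, k) cell with the integrated silhouette score
   SS_INT — the mean of the silhouette measured in the low-dimensional
   embedding and the silhouette of the same partition measured in the
   standardized high-dimensional feature space — and
4. for the best cell at a given k, picks one representative frame per
   cluster as the member sitting in the highest-density region of the
   latent space (per-cluster Gaussian KDE, Scott bandwidth).

The selected frames form the clustered ensemble (CE).  The baselines are the
sequential ensemble (SE) of equal size — evenly strided frames with a median
offset — and the GROMOS ensemble whose size emerges from an RMSD cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .cluster import ClusterLabels, agglomerative_ward, gromos_cluster, silhouette
from .dimred import Embedding, standardize, tsne
from .fingerprints import FeatureMatrix
from .traj import AtomSelection, ConformationSet

__all__ = [
    "ScanResult",
    "EnsembleSpec",
    "ss_int_scan",
    "select_best",
    "density_centers",
    "sequential_ensemble",
    "gromos_ensemble",
]


def integrate_silhouettes(ss_low: float, ss_high: float) -> float:
    """SS_INT: combination of the low- and high-dimensional silhouettes.

    The arithmetic mean weights partition quality in the embedding and in
    the original feature space equally; isolated here so the combination
    rule can be swapped in one place.
    """
    return 0.5 * (ss_low + ss_high)


@dataclass
class ScanResult:
    """SS_INT over a (perplexity × ensemble size) grid, with the artifacts
    needed to reuse the winning cell (embeddings and partitions)."""

    perplexities: list[float]
    ks: list[int]
    ss_low: np.ndarray    # (n_p, n_k)
    ss_high: np.ndarray
    ss_int: np.ndarray
    valid: np.ndarray     # bool mask, False where tSNE failed
    embeddings: dict[float, Embedding]
    labels: dict[tuple[float, int], ClusterLabels]
    seed: int = 0
    fingerprint_kind: str | None = None


@dataclass
class EnsembleSpec:
    """A designed ensemble: selected frame indices with optional weights.

    kind is CE (clustered), SE (sequential) or GROMOS_CE; provenance records
    fingerprint kind, DR method, perplexity, k and seed where applicable.
    """

    frame_indices: np.ndarray
    kind: str
    weights: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        order = np.argsort(self.frame_indices)
        self.frame_indices = self.frame_indices[order]
        if np.unique(self.frame_indices).size != self.frame_indices.size:
            raise ValueError("ensemble frame indices must be unique")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)[order]
            if np.any(self.weights <= 0):
                raise ValueError("ensemble weights must be positive")
            if abs(self.weights.sum() - 1.0) > 1e-9:
                raise ValueError("ensemble weights must sum to 1")

    @property
    def k(self) -> int:
        return self.frame_indices.size


def ss_int_scan(fm: FeatureMatrix, perplexities, ks, seed: int = 0,
                embedder=None, **tsne_kwargs) -> ScanResult:
    """Scan tSNE perplexities × ensemble sizes, scoring each cell by SS_INT.

    For each perplexity the standardized features are embedded once; for
    each k the embedding is partitioned by Ward agglomeration, and the cell
    scores ss_low (silhouette in the embedding), ss_high (silhouette of the
    same partition in the standardized feature space) and their combination
    ss_int.  A failing embedding invalidates its cells but the scan
    continues; a scan with no valid cell raises.

    ``embedder`` overrides the DR step (signature ``f(fm, perplexity, seed)
    -> Embedding``); the default is :func:`idpens.dimred.tsne`.
    """
    perplexities = list(perplexities)
    ks = list(ks)
    if not perplexities or not ks:
        raise ValueError("perplexity and k grids must be non-empty")
    if any(k < 2 for k in ks):
        raise ValueError("every ensemble size k must be >= 2")
    fm_std = fm if fm.standardized else standardize(fm)
    n_p, n_k = len(perplexities), len(ks)
    ss_low = np.full((n_p, n_k), np.nan)
    ss_high = np.full((n_p, n_k), np.nan)
    ss_int = np.full((n_p, n_k), np.nan)
    valid = np.zeros((n_p, n_k), dtype=bool)
    embeddings: dict[float, Embedding] = {}
    labels: dict[tuple[float, int], ClusterLabels] = {}
    for i, p in enumerate(perplexities):
        try:
            if embedder is not None:
                emb = embedder(fm_std, p, seed)
            else:
                emb, _ = tsne(fm_std, perplexity=p, seed=seed, **tsne_kwargs)
        except Exception as exc:  # a bad cell must not kill the scan
            warnings.warn(f"embedding failed at perplexity {p}: {exc}",
                          stacklevel=2)
            continue
        embeddings[p] = emb
        for j, k in enumerate(ks):
            lab = agglomerative_ward(emb, k)
            labels[(p, k)] = lab
            lo, _ = silhouette(emb, lab)
            hi, _ = silhouette(fm_std, lab)
            ss_low[i, j] = lo
            ss_high[i, j] = hi
            ss_int[i, j] = integrate_silhouettes(lo, hi)
            valid[i, j] = True
    if not valid.any():
        raise RuntimeError("every scan cell failed")
    return ScanResult(perplexities, ks, ss_low, ss_high, ss_int, valid,
                      embeddings, labels, seed=seed,
                      fingerprint_kind=fm.kind)


def select_best(scan: ScanResult, k: int):
    """Best perplexity at ensemble size k by SS_INT (ties → lowest p).

    Returns (p*, embedding, labels) for the winning cell.
    """
    if k not in scan.ks:
        raise ValueError(f"k={k} not in scan grid {scan.ks}")
    j = scan.ks.index(k)
    col = scan.ss_int[:, j]
    ok = scan.valid[:, j]
    if not ok.any():
        raise RuntimeError(f"no valid scan cell at k={k}")
    masked = np.where(ok, col, -np.inf)
    i = int(np.argmax(masked))  # first max -> lowest perplexity on ties
    p = scan.perplexities[i]
    return p, scan.embeddings[p], scan.labels[(p, k)]


def density_centers(emb: Embedding, labels: ClusterLabels,
                    provenance: dict | None = None) -> EnsembleSpec:
    """One representative frame per cluster from latent-space density.

    Within each cluster a Gaussian KDE (Scott bandwidth) is fit to that
    cluster's latent points and the member with maximal density is the
    center; this avoids picking outliers, unlike centroid-proximity rules.
    Ties and degenerate clusters (all points identical) resolve to the
    lowest frame index.  Weights are cluster populations / n.
    """
    pts = emb.points
    n = pts.shape[0]
    centers = []
    weights = []
    for c in range(labels.k):
        members = np.nonzero(labels.labels == c)[0]
        weights.append(members.size / n)
        if members.size == 1:
            centers.append(int(members[0]))
            continue
        cluster_pts = pts[members]
        try:
            kde = gaussian_kde(cluster_pts.T)  # Scott's rule
            dens = kde(cluster_pts.T)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"cluster {c}: degenerate point cloud, using lowest frame index",
                stacklevel=2,
            )
            centers.append(int(members[0]))
            continue
        best = int(members[int(np.argmax(dens))])  # first max -> lowest frame
        centers.append(best)
    return EnsembleSpec(
        np.asarray(centers), "CE", weights=np.asarray(weights),
        provenance=dict(provenance or {}),
    )


def sequential_ensemble(n_frames: int, k: int) -> EnsembleSpec:
    """Evenly strided frames with a median offset: the traditional baseline.

    stride = ⌊n/k⌋ and indices stride//2 + i·stride, i = 0..k−1, so each
    picked frame sits at the median of its stride window.  Uniform weights.
    """
    if not (1 <= k <= n_frames):
        raise ValueError(f"need 1 <= k <= n_frames, got k={k}, n={n_frames}")
    stride = n_frames // k
    indices = stride // 2 + stride * np.arange(k)
    return EnsembleSpec(indices, "SE", weights=np.full(k, 1.0 / k),
                        provenance={"n_frames": n_frames, "k": k})


def gromos_ensemble(cset: ConformationSet, cutoff: float,
                    selection: AtomSelection | None = None) -> EnsembleSpec:
    """GROMOS cluster centers as an ensemble; k emerges from the cutoff."""
    labels = gromos_cluster(cset, cutoff, selection=selection)
    pops = labels.populations().astype(float)
    order_weights = pops[np.arange(labels.k)] / labels.labels.size
    return EnsembleSpec(
        labels.centers_hint, "GROMOS_CE", weights=order_weights,
        provenance={"cutoff_nm": cutoff, "k": labels.k},
    )
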