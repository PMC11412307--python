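"""Dimensionality reduction of fingerprint matrices to 2-D latent spaces.

Linear methods: PCA (scikit-learn) and tICA — the time-lagged independent
component analysis, which solves the symmetrized generalized eigenproblem of
the lag-τ covariance against the instantaneous covariance so that the leading
components are the slowest-decorrelating linear combinations of features.

Nonlinear method: tSNE, implemented here in its exact O(n²) form so that the
perplexity calibration (per-row bisection of the Gaussian bandwidth), the
deterministic PCA initialization and the final KL divergence are all part of
the contract.  Runs are fully deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.decomposition import PCA as _SKPCA

from .fingerprints import FeatureMatrix

__all__ = [
    "Embedding",
    "standardize",
    "pca",
    "tica",
    "tsne",
    "conditional_probabilities",
]

_EPS = 1e-12


@dataclass
class Embedding:
    """frames × d latent coordinates with method tag and hyperparameters."""

    points: np.ndarray
    method: str  # PCA | TICA | TSNE
    hyperparams: dict = field(default_factory=dict)
    source_kind: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise ValueError("embedding points must be 2-D")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("embedding contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]


def standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Zero-mean, unit-variance columns (population σ).

    Zero-variance columns carry no conformational signal and are dropped
    with a warning; an all-constant matrix is an error.
    """
    if fm.n_frames < 2:
        raise ValueError("standardization requires at least 2 frames")
    mean = fm.values.mean(axis=0)
    sd = fm.values.std(axis=0)  # population
    keep = sd > 0
    if not np.any(keep):
        raise ValueError("all feature columns have zero variance")
    if not np.all(keep):
        dropped = [fm.column_labels[j] for j in np.nonzero(~keep)[0]]
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
    values = (fm.values[:, keep] - mean[keep]) / sd[keep]
    labels = [fm.column_labels[j] for j in np.nonzero(keep)[0]]
    return FeatureMatrix(values, fm.kind, labels, standardized=True)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(fm: FeatureMatrix, d: int = 2):
    """Principal component analysis.

    Returns (Embedding, loadings, explained_variance): loadings are the
    orthonormal component vectors (d × n_features), explained variances are
    non-increasing, and scores are the centered data projected on them.
    """
    if d > fm.n_features:
        raise ValueError(f"d={d} exceeds n_features={fm.n_features}")
    model = _SKPCA(n_components=d, svd_solver="full")
    scores = model.fit_transform(fm.values)
    emb = Embedding(scores, "PCA", {"d": d}, source_kind=fm.kind)
    return emb, model.components_, model.explained_variance_


# ---------------------------------------------------------------------------
# tICA
# ---------------------------------------------------------------------------

def tica(fm: FeatureMatrix, lag: int = 10, d: int = 2,
         ridge: float = 1e-5):
    """Time-lagged independent component analysis.

    Solves C_τ v = λ C_0 v with the symmetrized lagged covariance
    C_τ = ½⟨x_t x_{t+τ}ᵀ + x_{t+τ} x_tᵀ⟩ and the instantaneous covariance
    C_0, both estimated over the overlapping window and centered.  C_0 is
    regularized by ``ridge``·tr(C_0)/n_features on the diagonal.  Components
    are sorted by decreasing eigenvalue and normalized so that the projected
    series are uncorrelated with unit variance at lag 0.

    Returns (Embedding, eigenvalues).
    """
    n, p = fm.values.shape
    if not (1 <= lag < n):
        raise ValueError("require frames > lag >= 1")
    if d > p:
        raise ValueError(f"d={d} exceeds n_features={p}")
    x0 = fm.values[:-lag]
    xt = fm.values[lag:]
    mean = 0.5 * (x0.mean(axis=0) + xt.mean(axis=0))
    x0 = x0 - mean
    xt = xt - mean
    m = x0.shape[0]
    c0 = 0.5 * (x0.T @ x0 + xt.T @ xt) / m
    ct = 0.5 * (x0.T @ xt + xt.T @ x0) / m
    if ridge > 0:
        c0 = c0 + np.eye(p) * ridge * np.trace(c0) / p
    else:
        # without regularization a singular C_0 makes the problem ill-posed
        if np.linalg.matrix_rank(c0) < p:
            raise np.linalg.LinAlgError(
                "instantaneous covariance is singular; set ridge > 0"
            )
    eigvals, eigvecs = scipy.linalg.eigh(ct, c0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order][:d]
    # eigh(b=...) normalizes v^T C_0 v = I -> unit-variance, uncorrelated tICs
    components = eigvecs[:, order][:, :d]
    scores = (fm.values - fm.values.mean(axis=0)) @ components
    emb = Embedding(scores, "TICA", {"lag": lag, "d": d, "ridge": ridge},
                    source_kind=fm.kind)
    return emb, eigvals


# ---------------------------------------------------------------------------
# tSNE (exact)
# ---------------------------------------------------------------------------

def conditional_probabilities(sq_distances: np.ndarray, perplexity: float,
                              tol: float = 1e-5, max_iter: int = 100):
    """Per-row Gaussian conditional probabilities calibrated to a perplexity.

    For each row i the precision β_i is found by bisection so that the
    Shannon entropy H of p_{j|i} satisfies 2^H = perplexity (within ``tol``
    on H, comfortably tighter than 1e-3 on the perplexity itself).

    Returns (P, betas) with P_ii = 0 and each row summing to 1.
    """
    n = sq_distances.shape[0]
    target = np.log(perplexity)
    P = np.zeros((n, n))
    betas = np.ones(n)
    for i in range(n):
        d = np.delete(sq_distances[i], i)
        d = d - d.min()  # shift-invariant for p; avoids exp underflow
        lo, hi = -np.inf, np.inf
        beta = 1.0
        for _ in range(max_iter):
            w = np.exp(-d * beta)
            s = w.sum()
            p = w / s
            h = beta * float(np.sum(d * p)) + np.log(s)
            if abs(h - target) < tol:
                break
            if h > target:  # entropy too high -> narrow the kernel
                lo = beta
                beta = beta * 2.0 if not np.isfinite(hi) else 0.5 * (beta + hi)
            else:
                hi = beta
                beta = beta / 2.0 if not np.isfinite(lo) else 0.5 * (beta + lo)
        w = np.exp(-d * beta)
        row = np.zeros(n)
        row[np.arange(n) != i] = w / w.sum()
        P[i] = row
        betas[i] = beta
    return P, betas


def _kl_divergence(P: np.ndarray, Y: np.ndarray) -> float:
    Q, _ = _student_t_q(Y)
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / np.maximum(Q[mask], _EPS))))


def _student_t_q(Y: np.ndarray):
    num = 1.0 / (1.0 + _squared_distances(Y))
    np.fill_diagonal(num, 0.0)
    Q = num / num.sum()
    return np.maximum(Q, _EPS), num


def tsne(fm: FeatureMatrix, perplexity: float = 30.0, seed: int = 0,
         d: int = 2, iterations: int = 1000,
         learning_rate: float | None = None,
         early_exaggeration: float = 12.0, init: str = "pca"):
    """Exact tSNE embedding of a feature matrix.

    Gradient descent on KL(P‖Q) with momentum (0.5, then 0.8 after the
    early-exaggeration phase of 250 iterations) and per-parameter gains.
    The default learning rate is n/12 and the default initialization is the
    first ``d`` PCA scores scaled to σ=1e-4, which makes the embedding
    deterministic; with ``init="random"`` the seed controls the start.

    Returns (Embedding, final_kl); the reported KL always refers to the
    un-exaggerated P and never exceeds the KL of the initial layout.
    """
    X = fm.values
    n = X.shape[0]
    if not (1.0 < perplexity < (n - 1) / 3.0):
        raise ValueError(
            f"perplexity must satisfy 1 < p < (n-1)/3 = {(n - 1) / 3:.1f}"
        )
    lr = learning_rate if learning_rate is not None else n / 12.0
    d2 = _squared_distances(X)
    P_cond, _ = conditional_probabilities(d2, perplexity)
    P = (P_cond + P_cond.T) / (2.0 * n)
    P = np.maximum(P, _EPS)

    rng = np.random.default_rng(seed)
    if init == "pca":
        model = _SKPCA(n_components=d, svd_solver="full")
        Y = model.fit_transform(X)
        Y = Y / max(Y[:, 0].std(), _EPS) * 1e-4
    elif init == "random":
        Y = rng.standard_normal((n, d)) * 1e-4
    else:
        raise ValueError("init must be 'pca' or 'random'")

    initial_kl = _kl_divergence(P, Y)
    best_Y, best_kl = Y.copy(), initial_kl

    exag_iters = min(250, iterations)
    update = np.zeros_like(Y)
    gains = np.ones_like(Y)
    for it in range(iterations):
        Pe = P * early_exaggeration if it < exag_iters else P
        Q, num = _student_t_q(Y)
        W = (Pe - num / num.sum()) * num
        grad = 4.0 * ((np.diag(W.sum(axis=1)) - W) @ Y)
        momentum = 0.5 if it < exag_iters else 0.8
        inc = np.sign(grad) != np.sign(update)
        gains = np.where(inc, gains + 0.2, gains * 0.8)
        gains = np.maximum(gains, 0.01)
        update = momentum * update - lr * gains * grad
        Y = Y + update
        Y = Y - Y.mean(axis=0)
    final_kl = _kl_divergence(P, Y)
    if final_kl > best_kl:  # guard against a divergent step size
        Y, final_kl = best_Y, best_kl
    emb = Embedding(
        Y, "TSNE",
        {"perplexity": perplexity, "seed": seed, "d": d,
         "iterations": iterations, "learning_rate": lr, "init": init},
        source_kind=fm.kind,
    )
    return emb, final_kl


def _squared_distances(X: np.ndarray) -> np.ndarray:
    s = np.sum(X ** 2, axis=1)
    d2 = s[:, None] + s[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)
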