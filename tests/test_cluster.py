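import itertools

import numpy as np
import pytest

from conftest import make_cset
from idpens import (
    AtomSelection,
    ClusterLabels,
    agglomerative_ward,
    davies_bouldin,
    generate_trajectory,
    gromos_cluster,
    gromos_from_distances,
    kmeans,
    pairwise_rmsd,
    silhouette,
    three_state_spec,
)


# ------------------------------------------------------------------ oracles

def brute_force_silhouette(X, labels):
    """O(n²) direct-formula silhouette with the singleton-0 convention."""
    n = len(X)
    D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
    scores = np.zeros(n)
    for i in range(n):
        mine = labels == labels[i]
        if mine.sum() == 1:
            continue
        a = D[i, mine & (np.arange(n) != i)].mean()
        b = min(D[i, labels == c].mean()
                for c in np.unique(labels) if c != labels[i])
        scores[i] = (b - a) / max(a, b)
    return scores.mean(), scores


def brute_force_davies_bouldin(X, labels):
    ks = np.unique(labels)
    cents = np.array([X[labels == c].mean(axis=0) for c in ks])
    S = np.array([np.linalg.norm(X[labels == c] - cents[j], axis=1).mean()
                  for j, c in enumerate(ks)])
    total = 0.0
    for i in range(len(ks)):
        total += max((S[i] + S[j]) / np.linalg.norm(cents[i] - cents[j])
                     for j in range(len(ks)) if j != i)
    return total / len(ks)


def brute_force_ward_partitions(X):
    """Greedy Ward agglomeration by direct evaluation of the variance
    increase; returns the partition (set of frozensets) at every k."""
    clusters = [{i} for i in range(len(X))]
    partitions = {len(X): {frozenset(c) for c in clusters}}
    while len(clusters) > 1:
        best = None
        for (i, a), (j, b) in itertools.combinations(enumerate(clusters), 2):
            ca, cb = X[list(a)].mean(axis=0), X[list(b)].mean(axis=0)
            delta = len(a) * len(b) / (len(a) + len(b)) * np.sum((ca - cb) ** 2)
            key = (delta, i, j)
            if best is None or key < best:
                best = key
                merge = (i, j)
        i, j = merge
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
        partitions[len(clusters)] = {frozenset(c) for c in clusters}
    return partitions


# ------------------------------------------------------------------ kmeans

def test_kmeans_trivial_cases(rng):
    X = rng.normal(size=(20, 2))
    labels, inertia = kmeans(X, 1, seed=0)
    assert labels.k == 1
    assert inertia == pytest.approx(np.sum((X - X.mean(axis=0)) ** 2))
    labels_n, inertia_n = kmeans(X, 20, seed=0)
    assert inertia_n == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        kmeans(np.zeros((5, 2)), 2, seed=0)


def test_kmeans_recovers_planted_blobs(rng):
    from sklearn.metrics import adjusted_rand_score

    X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(10, 1, (50, 2))])
    truth = np.repeat([0, 1], 50)
    labels, _ = kmeans(X, 2, seed=3)
    assert adjusted_rand_score(truth, labels.labels) == 1.0


# -------------------------------------------------------------------- Ward

def test_ward_singletons(rng):
    X = rng.normal(size=(6, 2))
    labels = agglomerative_ward(X, 6)
    assert labels.k == 6
    assert len(set(labels.labels)) == 6


def test_ward_recovers_tight_triplets(rng):
    centers = np.array([[0, 0], [100, 0], [0, 100.0]])
    X = np.vstack([c + rng.normal(0, 0.1, (3, 2)) for c in centers])
    labels = agglomerative_ward(X, 3)
    parts = {frozenset(np.nonzero(labels.labels == c)[0].tolist())
             for c in range(3)}
    assert parts == {frozenset({0, 1, 2}), frozenset({3, 4, 5}),
                     frozenset({6, 7, 8})}


@pytest.mark.parametrize("n", [5, 7, 8])
def test_ward_matches_exhaustive_oracle(n, rng):
    X = rng.normal(size=(n, 3))
    oracle = brute_force_ward_partitions(X)
    for k in range(1, n + 1):
        labels = agglomerative_ward(X, k)
        got = {frozenset(np.nonzero(labels.labels == c)[0].tolist())
               for c in range(k)}
        assert got == oracle[k], f"partition mismatch at k={k}"


def test_ward_k_validation(rng):
    with pytest.raises(ValueError):
        agglomerative_ward(rng.normal(size=(4, 2)), 5)


# ------------------------------------------------------------------ GROMOS

def test_gromos_hand_traced_partition():
    x = np.array([0.0, 1.0, 2.0, 10.0, 11.0])
    D = np.abs(x[:, None] - x[None, :])
    labels = gromos_from_distances(D, cutoff=1.5)
    assert labels.k == 2
    np.testing.assert_array_equal(labels.labels, [0, 0, 0, 1, 1])
    np.testing.assert_array_equal(labels.centers_hint, [1, 3])


def test_gromos_degenerate_cutoffs(rng):
    spec = three_state_spec(n_frames=12, n_residues=6, seed=0)
    cset, _ = generate_trajectory(spec)
    D = pairwise_rmsd(cset)
    wide = gromos_cluster(cset, cutoff=D.max() + 1.0)
    assert wide.k == 1
    off = D[~np.eye(len(D), dtype=bool)]
    narrow = gromos_cluster(cset, cutoff=off.min() * 0.5)
    assert narrow.k == cset.n_frames


def test_gromos_members_within_cutoff_of_center():
    spec = three_state_spec(n_frames=30, n_residues=6, seed=4)
    cset, _ = generate_trajectory(spec)
    D = pairwise_rmsd(cset)
    cutoff = np.median(D)
    labels = gromos_cluster(cset, cutoff=cutoff)
    for c in range(labels.k):
        center = labels.centers_hint[c]
        members = np.nonzero(labels.labels == c)[0]
        assert np.all(D[center, members] <= cutoff + 1e-12)


def test_gromos_cutoff_validation():
    with pytest.raises(ValueError):
        gromos_from_distances(np.zeros((3, 3)), cutoff=0.0)


def test_pairwise_rmsd_symmetric_zero_diagonal(rng):
    spec = three_state_spec(n_frames=8, n_residues=5, seed=1)
    cset, _ = generate_trajectory(spec)
    D = pairwise_rmsd(cset, AtomSelection.all_atoms())
    np.testing.assert_allclose(D, D.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)
    # spot-check one pair against the single-pair Kabsch
    from idpens.descriptors import _kabsch_rmsd

    sel = AtomSelection.all_atoms().resolve(cset)
    want = _kabsch_rmsd(cset.coords[2, sel], cset.coords[5, sel])
    assert D[2, 5] == pytest.approx(want, abs=1e-8)


# ----------------------------------------------------------------- indices

def test_silhouette_hand_case_and_singletons():
    X = np.array([[0.0], [0.1], [10.0], [10.1]])
    lab = ClusterLabels(np.array([0, 0, 1, 1]), 2, "KMEANS")
    mean_s, per = silhouette(X, lab)
    oracle_mean, oracle_per = brute_force_silhouette(X, lab.labels)
    assert mean_s == pytest.approx(0.99, abs=1e-3)
    np.testing.assert_allclose(per, oracle_per, atol=1e-10)

    singles = ClusterLabels(np.arange(4), 4, "KMEANS")
    mean_s, per = silhouette(X, singles)
    assert mean_s == 0.0
    np.testing.assert_array_equal(per, 0.0)


def test_silhouette_matches_bruteforce_oracle(rng):
    X = rng.normal(size=(50, 3))
    raw = rng.integers(0, 4, size=50)
    lab = ClusterLabels(_canon(raw), 4, "KMEANS")
    mean_s, per = silhouette(X, lab)
    o_mean, o_per = brute_force_silhouette(X, lab.labels)
    assert mean_s == pytest.approx(o_mean, abs=1e-10)
    np.testing.assert_allclose(per, o_per, atol=1e-10)


def test_silhouette_precomputed_and_permutation_invariance(rng):
    X = rng.normal(size=(30, 2))
    raw = rng.integers(0, 3, size=30)
    lab = ClusterLabels(_canon(raw), 3, "KMEANS")
    D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
    m1, _ = silhouette(X, lab)
    m2, _ = silhouette(D, lab, precomputed=True)
    assert m1 == pytest.approx(m2, abs=1e-10)
    perm = _canon((lab.labels + 1) % 3)
    m3, _ = silhouette(X, ClusterLabels(perm, 3, "KMEANS"))
    assert m1 == pytest.approx(m3, abs=1e-12)


def _canon(raw):
    """Relabel to 0..k-1 in order of first appearance (ClusterLabels needs
    every label used)."""
    mapping = {}
    return np.array([mapping.setdefault(int(v), len(mapping)) for v in raw])


def test_davies_bouldin_hand_case_and_oracle(rng):
    X = np.array([[0.0], [0.1], [10.0], [10.1]])
    lab = ClusterLabels(np.array([0, 0, 1, 1]), 2, "KMEANS")
    # S_1 = S_2 = 0.05; centroids 0.05 and 10.05 -> M = 10.0
    got = davies_bouldin(X, lab)
    assert got == pytest.approx(0.1 / 10.0, abs=1e-10)
    assert got == pytest.approx(brute_force_davies_bouldin(X, lab.labels),
                                abs=1e-12)
    Y = rng.normal(size=(40, 2))
    raw = _canon(rng.integers(0, 3, size=40))
    lab2 = ClusterLabels(raw, 3, "KMEANS")
    assert davies_bouldin(Y, lab2) == pytest.approx(
        brute_force_davies_bouldin(Y, raw), abs=1e-10)


def test_davies_bouldin_separation_limit(rng):
    base = rng.normal(0, 0.1, (10, 2))
    prev = np.inf
    for sep in (10.0, 100.0, 1000.0):
        X = np.vstack([base, base + [sep, 0.0]])
        lab = ClusterLabels(np.repeat([0, 1], 10), 2, "KMEANS")
        score = davies_bouldin(X, lab)
        assert score < prev
        prev = score
    assert prev < 1e-3


def test_davies_bouldin_coincident_centroids():
    X = np.array([[0.0, 0], [0, 0], [0, 0], [0, 0]])
    lab = ClusterLabels(np.array([0, 0, 1, 1]), 2, "KMEANS")
    with pytest.raises(ZeroDivisionError):
        davies_bouldin(X, lab)
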