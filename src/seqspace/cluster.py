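"""Consensus K-means on factor scores, with silhouette model selection.

A single K-means run depends on its random initialization, so the protocol
here repeats the fit many times (1000 by default) from random initial
centroids, takes the most frequent partition (up to label permutation) as
the reference, and quantifies reproducibility as the fraction of runs in
which each element lands in its reference cluster.  The number of clusters
is selected by the run-averaged mean silhouette width over a range of K.

The K-means step itself is deliberately plain Lloyd iteration: random
initial centroids (D²-weighted sampling of data points by default; plain
uniform sampling available via ``init='random'``), assignments by Euclidean
distance, convergence when assignments stabilize, an empty cluster
re-seeded at the point farthest from its current centroid.  The surrounding
consensus protocol — not the base algorithm — is what the module is for;
a library K-means is used as a cross-check in the test suite, not here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_samples
from sklearn.utils.validation import check_is_fitted


def _init_centers(
    X: np.ndarray, k: int, rng: np.random.Generator, init: str
) -> np.ndarray:
    """Random initial centroids: plain uniform sampling of data points, or
    D²-weighted (k-means++) sampling.

    With ``init='random'`` and k well-separated clusters, the chance that
    the k sampled points cover all clusters is only k!/k^k, so run-to-run
    reproducibility depends on fragile basin geometry; the D²-weighted
    draw spreads the initial centroids and makes the repeated protocol
    reproduce a dominant modal partition, which is why it is the default.
    """
    n = X.shape[0]
    if init == "random":
        return X[rng.choice(n, size=k, replace=False)].copy()
    if init != "k-means++":
        raise ValueError(f"unknown init {init!r}")
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = d2.sum()
        if total == 0:
            centers[c:] = X[rng.choice(n, size=k - c, replace=False)]
            break
        centers[c] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[c]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 300,
    init: str = "k-means++",
):
    """One Lloyd K-means run; returns canonicalized labels."""
    n = X.shape[0]
    centers = _init_centers(X, k, rng, init)
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new = d2.argmin(axis=1)
        # re-seed empty clusters at the farthest point from its centroid,
        # repeating until every cluster holds at least one point
        empties = np.setdiff1d(np.arange(k), np.unique(new))
        guard = 0
        while empties.size and guard < 2 * k:
            guard += 1
            empty = empties[0]
            far = d2[np.arange(n), new].argmax()
            centers[empty] = X[far]
            d2[:, empty] = ((X - centers[empty]) ** 2).sum(axis=1)
            new = d2.argmin(axis=1)
            empties = np.setdiff1d(np.arange(k), np.unique(new))
        if np.array_equal(new, labels):
            break
        labels = new
        for c in range(k):
            members = labels == c
            if members.any():
                centers[c] = X[members].mean(axis=0)
    return _canonicalize(labels)


def _canonicalize(labels: np.ndarray) -> np.ndarray:
    """Renumber clusters by order of first appearance (label-permutation invariant)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _match_to_reference(labels: np.ndarray, reference: np.ndarray, k: int) -> np.ndarray:
    """Relabel a run's clusters to best agree with the reference partition."""
    contingency = np.zeros((k, k))
    np.add.at(contingency, (labels, reference), 1)
    run_idx, ref_idx = linear_sum_assignment(-contingency)
    remap = np.empty(k, dtype=int)
    remap[run_idx] = ref_idx
    return remap[labels]


def _mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    if len(np.unique(labels)) < 2:
        return 0.0
    return float(silhouette_samples(D, labels, metric="precomputed").mean())


@dataclass(frozen=True)
class ClusteringResult:
    """Modal partition of repeated K-means and its reproducibility."""

    K: int
    modal_labels: np.ndarray
    frequency: float  # fraction of runs matching the modal partition exactly
    per_id_stability: np.ndarray  # fraction of runs each id is in its modal cluster
    runs: int
    seed: int | None
    ids: tuple[str, ...] | None = None


class ConsensusKMeans(ClusterMixin, BaseEstimator):
    """Repeated K-means with modal-partition consensus.

    Parameters
    ----------
    n_clusters : int
        K.
    n_runs : int
        Number of independent Lloyd runs with random initial centroids.
    random_state : int or None
        Seed; the whole protocol is reproducible bit-for-bit given it.
    max_iter : int
        Lloyd iteration cap per run.
    init : {"k-means++", "random"}
        How the random initial centroids are drawn (see ``_init_centers``).

    Attributes
    ----------
    labels_ : modal (most frequent) partition, clusters numbered by first
        appearance.
    modal_frequency_ : fraction of runs whose partition equals the modal one.
    per_id_stability_ : per-element fraction of runs assigned to the modal
        cluster (after optimal label matching per run).
    cluster_centers_ : centroids of the modal partition.
    """

    def __init__(
        self,
        n_clusters: int = 4,
        n_runs: int = 1000,
        random_state: int | None = None,
        max_iter: int = 300,
        init: str = "k-means++",
    ):
        self.n_clusters = n_clusters
        self.n_runs = n_runs
        self.random_state = random_state
        self.max_iter = max_iter
        self.init = init

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (elements x components)")
        n = X.shape[0]
        k = self.n_clusters
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        if k > n:
            raise ValueError(f"n_clusters={k} exceeds the {n} data points")
        rng = np.random.default_rng(self.random_state)
        if k == 1:
            all_runs = [np.zeros(n, dtype=int)] * self.n_runs
        else:
            all_runs = [
                _lloyd(X, k, rng, self.max_iter, self.init)
                for _ in range(self.n_runs)
            ]
        counts = Counter(run.tobytes() for run in all_runs)
        top = max(counts.values())
        tied = [key for key, c in counts.items() if c == top]
        if len(tied) > 1:
            # break ties by the highest within-run mean silhouette
            D = _pairwise(X)
            tied.sort(
                key=lambda key: -_mean_silhouette(
                    D, np.frombuffer(key, dtype=all_runs[0].dtype)
                )
            )
        modal = np.frombuffer(tied[0], dtype=all_runs[0].dtype).copy()
        stability = np.zeros(n)
        for run in all_runs:
            matched = _match_to_reference(run, modal, k) if k > 1 else run
            stability += matched == modal
        stability /= self.n_runs

        self.labels_ = modal
        self.modal_frequency_ = counts[modal.tobytes()] / self.n_runs
        self.per_id_stability_ = stability
        self.cluster_centers_ = np.vstack(
            [X[modal == c].mean(axis=0) for c in range(k)]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def _pairwise(X: np.ndarray) -> np.ndarray:
    sq = (X**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


def repeated_kmeans(
    scores: np.ndarray,
    K: int,
    runs: int = 1000,
    seed: int | None = None,
    ids: tuple[str, ...] | None = None,
    init: str = "k-means++",
) -> ClusteringResult:
    """Run the consensus K-means protocol and package the result."""
    est = ConsensusKMeans(
        n_clusters=K, n_runs=runs, random_state=seed, init=init
    ).fit(scores)
    return ClusteringResult(
        K=K,
        modal_labels=est.labels_,
        frequency=est.modal_frequency_,
        per_id_stability=est.per_id_stability_,
        runs=runs,
        seed=seed,
        ids=ids,
    )


@dataclass(frozen=True)
class SilhouetteProfile:
    """Run-averaged mean silhouette width per candidate K."""

    K_values: tuple[int, ...]
    mean_silhouette: np.ndarray
    best_K: int  # argmax over K >= 2 (K=1 is pinned to 0 by convention)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"K": self.K_values, "mean_silhouette": self.mean_silhouette}
        )


def silhouette_profile(
    scores: np.ndarray,
    K_range=range(1, 14),
    runs: int = 1000,
    seed: int | None = None,
    init: str = "k-means++",
) -> SilhouetteProfile:
    """Mean silhouette width per K, averaged over repeated K-means runs.

    The silhouette is undefined for a single cluster; K=1 is reported as 0
    and excluded from the argmax.
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    Ks = tuple(int(k) for k in K_range)
    if max(Ks) > n - 1:
        raise ValueError("max K must be <= n - 1 for the silhouette to be defined")
    rng = np.random.default_rng(seed)
    D = _pairwise(X)
    means = np.zeros(len(Ks))
    for idx, k in enumerate(Ks):
        if k == 1:
            means[idx] = 0.0
            continue
        total = 0.0
        for _ in range(runs):
            labels = _lloyd(X, k, rng, init=init)
            total += _mean_silhouette(D, labels)
        means[idx] = total / runs
    eligible = [i for i, k in enumerate(Ks) if k >= 2]
    best = Ks[max(eligible, key=lambda i: means[i])]
    return SilhouetteProfile(Ks, means, best)
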