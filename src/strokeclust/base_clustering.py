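"""The eight-method clustering ensemble and its co-association consensus.

Eight classical clustering algorithms — fuzzy c-means, k-means, a 1 x k
self-organizing map, Gaussian mixtures, DBSCAN, agglomerative (Ward),
spectral, and OPTICS — are run under one uniform contract: same feature
matrix, seeded, returning an integer partition.  Each partition yields a
binary connectivity matrix (1 where two subjects share a cluster); the
element-wise mean over the ensemble is the consensus (co-association)
matrix handed to the tri-factor NMF combiner.

Fuzzy c-means and the linear SOM are implemented here directly; they are
short, standard algorithms and keeping them in-package keeps the ensemble
contract (seeding, hardening, tie-breaks) explicit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import DBSCAN, OPTICS, AgglomerativeClustering, KMeans, SpectralClustering
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from .errors import ConfigurationError, DataError, InputError
from .preprocess import FeatureMatrix

METHOD_NAMES = (
    "fuzzy-c-means",
    "k-means",
    "som",
    "gmm",
    "dbscan",
    "hierarchical",
    "spectral",
    "optics",
)
_ALIASES = {"kmeans": "k-means", "fcm": "fuzzy-c-means"}


@dataclass(frozen=True)
class MethodSpec:
    name: str
    params: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        canonical = _ALIASES.get(self.name, self.name)
        object.__setattr__(self, "name", canonical)
        if canonical not in METHOD_NAMES:
            raise ConfigurationError(
                f"unknown method {self.name!r}; expected one of {METHOD_NAMES}"
            )


@dataclass(frozen=True)
class BasePartition:
    """One base clustering result: the method that produced it plus labels."""

    method: MethodSpec
    labels: np.ndarray
    n_clusters_found: int


@dataclass(frozen=True)
class ConsensusMatrix:
    """Symmetric co-association matrix with entries in [0, 1], unit diagonal."""

    values: np.ndarray
    n_partitions: int

    @property
    def n(self) -> int:
        return self.values.shape[0]


def default_method_specs(seed: int = 0) -> tuple[MethodSpec, ...]:
    """One spec per method with shared default hyperparameters.

    The same specs (same seeds included) are used by every client so all
    clients start from identical initialization parameters.
    """
    return tuple(MethodSpec(name=n, seed=seed + i) for i, n in enumerate(METHOD_NAMES))


# ---------------------------------------------------------------------------
# in-package implementations


def _fuzzy_c_means(X, k, seed, m=2.0, max_iter=300, tol=1e-5):
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    U = rng.dirichlet(np.ones(k), size=n)
    for _ in range(max_iter):
        Um = U**m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = cdist(X, centers, "sqeuclidean") + 1e-12
        inv = d2 ** (-1.0 / (m - 1.0))
        U_new = inv / inv.sum(axis=1, keepdims=True)
        shift = np.abs(U_new - U).max()
        U = U_new
        if shift < tol:
            break
    # harden by maximal membership; argmax takes the lowest index on ties
    return np.argmax(U, axis=1)


def _som_line(X, k, seed, n_epochs=20, lr=(0.5, 0.02), sigma=None):
    """Online SOM on a 1 x k map; each unit is one cluster."""
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    W = X[rng.choice(n, size=k, replace=False)].astype(float).copy()
    sig0, sig1 = sigma if sigma is not None else (max(k / 2.0, 1.0), 0.1)
    units = np.arange(k)
    total = max(n_epochs * n - 1, 1)
    step = 0
    for _ in range(n_epochs):
        for i in rng.permutation(n):
            frac = step / total
            eta = lr[0] * (lr[1] / lr[0]) ** frac
            sig = sig0 * (sig1 / sig0) ** frac
            bmu = int(np.argmin(((X[i] - W) ** 2).sum(axis=1)))
            h = np.exp(-((units - bmu) ** 2) / (2.0 * sig**2))
            W += eta * h[:, None] * (X[i] - W)
            step += 1
    return np.argmin(cdist(X, W, "sqeuclidean"), axis=1)


def _absorb_noise(X, labels):
    """Reassign density-method noise points (-1) to the nearest cluster centroid."""
    labels = labels.copy()
    noise = labels < 0
    if not noise.any():
        return labels
    if noise.all():
        return np.zeros_like(labels)
    keep = np.unique(labels[~noise])
    centroids = np.vstack([X[labels == c].mean(axis=0) for c in keep])
    nearest = np.argmin(cdist(X[noise], centroids, "sqeuclidean"), axis=1)
    labels[noise] = keep[nearest]
    return labels


def _compact_labels(labels):
    """Relabel to consecutive integers starting at 0, order of first appearance by value."""
    uniq = np.unique(labels)
    remap = {c: i for i, c in enumerate(uniq)}
    return np.array([remap[c] for c in labels], dtype=int)


# ---------------------------------------------------------------------------
# operations


def run_method(features: FeatureMatrix | np.ndarray, spec: MethodSpec, k: int) -> BasePartition:
    """Run one base method; deterministic for a fixed spec seed.

    Density methods (DBSCAN, OPTICS) ignore ``k``: their noise points are
    absorbed into the nearest found cluster and the partition is kept even
    when its cluster count differs from ``k`` — the consensus layer
    tolerates heterogeneous partitions.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    n = X.shape[0]
    if n < k:
        raise InputError(f"n={n} < k={k}")
    if not np.all(np.isfinite(X)):
        raise DataError("features contain non-finite values")
    if np.all(X.std(axis=0) == 0):
        raise DataError("degenerate features: zero variance in every column")
    p = dict(spec.params)
    name = spec.name

    if name == "k-means":
        labels = KMeans(
            n_clusters=k, random_state=spec.seed, n_init=p.pop("n_init", 10), **p
        ).fit_predict(X)
    elif name == "fuzzy-c-means":
        labels = _fuzzy_c_means(X, k, seed=spec.seed, **p)
    elif name == "som":
        labels = _som_line(X, k, seed=spec.seed, **p)
    elif name == "gmm":
        labels = GaussianMixture(
            n_components=k,
            covariance_type=p.pop("covariance_type", "diag"),
            random_state=spec.seed,
            reg_covar=p.pop("reg_covar", 1e-6),
            **p,
        ).fit_predict(X)
    elif name == "hierarchical":
        labels = AgglomerativeClustering(
            n_clusters=k, linkage=p.pop("linkage", "ward"), **p
        ).fit_predict(X)
    elif name == "spectral":
        labels = SpectralClustering(
            n_clusters=k,
            random_state=spec.seed,
            affinity=p.pop("affinity", "rbf"),
            n_init=p.pop("n_init", 10),
            **p,
        ).fit_predict(X)
    elif name == "dbscan":
        eps = p.pop("eps", None)
        if eps is None:
            # data-scaled default: half the median pairwise distance
            eps = 0.5 * float(np.median(pdist(X))) or 0.5
        labels = DBSCAN(eps=eps, min_samples=p.pop("min_samples", 3), **p).fit_predict(X)
        labels = _absorb_noise(X, labels)
    elif name == "optics":
        eps = p.pop("eps", None)
        if eps is None:
            eps = 0.5 * float(np.median(pdist(X))) or 0.5
        labels = OPTICS(
            min_samples=p.pop("min_samples", 3),
            cluster_method=p.pop("cluster_method", "dbscan"),
            eps=eps,
            **p,
        ).fit_predict(X)
        labels = _absorb_noise(X, labels)
    else:  # pragma: no cover - guarded by MethodSpec
        raise ConfigurationError(f"unknown method {name!r}")

    labels = _compact_labels(np.asarray(labels, dtype=int))
    return BasePartition(
        method=spec, labels=labels, n_clusters_found=int(labels.max()) + 1
    )


def connectivity_matrix(partition: BasePartition | np.ndarray) -> np.ndarray:
    """Binary n x n matrix: entry (i, j) is 1 iff i and j share a cluster."""
    labels = partition.labels if isinstance(partition, BasePartition) else np.asarray(partition)
    return (labels[:, None] == labels[None, :]).astype(float)


def consensus_matrix(partitions: Sequence[BasePartition]) -> ConsensusMatrix:
    """Element-wise mean of the partitions' connectivity matrices."""
    if len(partitions) == 0:
        raise InputError("need at least one partition")
    n = len(partitions[0].labels)
    if any(len(p.labels) != n for p in partitions):
        raise InputError("all partitions must cover the same n points")
    cm = np.zeros((n, n))
    for p in partitions:
        cm += connectivity_matrix(p)
    cm /= len(partitions)
    return ConsensusMatrix(values=cm, n_partitions=len(partitions))


def _aligned_accuracy(pred, ref):
    """Accuracy under the best cluster-to-class matching (Hungarian)."""
    from scipy.optimize import linear_sum_assignment

    pred = np.asarray(pred)
    ref = np.asarray(ref)
    pu, ru = np.unique(pred), np.unique(ref)
    cost = np.zeros((len(pu), len(ru)))
    for a, c in enumerate(pu):
        for b, r in enumerate(ru):
            cost[a, b] = -np.sum((pred == c) & (ref == r))
    rows, cols = linear_sum_assignment(cost)
    return -cost[rows, cols].sum() / len(ref)


def exhaustive_search(
    features: FeatureMatrix | np.ndarray,
    method_pool: Sequence[MethodSpec],
    k: int,
    objective: str = "stability",
    reference: np.ndarray | None = None,
    mnmf_config=None,
):
    """Evaluate every non-empty subset of the method pool.

    For each subset the consensus matrix is built, the full tri-factor NMF
    consensus is fit, and the resulting labels are scored either by
    ``stability`` (mean adjusted Rand agreement between the consensus labels
    and each subset partition) or against supplied ``reference`` labels
    (best-matching accuracy).  Returns ``(best_specs, scores)`` where
    ``scores`` maps subset name tuples to their score; ties break toward
    the smaller, then lexicographically earlier, subset.
    """
    from .consensus import MNMFConfig, mnmf_fit

    if not 1 <= len(method_pool) <= 8:
        raise ConfigurationError("method_pool must contain between 1 and 8 methods")
    if objective not in ("stability", "reference"):
        raise ConfigurationError(f"unknown objective {objective!r}")
    if objective == "reference" and reference is None:
        raise ConfigurationError("reference labels required for the reference objective")
    cfg = mnmf_config or MNMFConfig(k=k, n_restarts=5, max_iter=200)

    partitions = [run_method(features, spec, k) for spec in method_pool]
    scores: dict[tuple[str, ...], float] = {}
    best = None
    for r in range(1, len(method_pool) + 1):
        for combo in itertools.combinations(range(len(method_pool)), r):
            subset = [partitions[i] for i in combo]
            cm = consensus_matrix(subset)
            result, _ = mnmf_fit(cm, features, cfg)
            if objective == "stability":
                s = float(
                    np.mean(
                        [adjusted_rand_score(p.labels, result.hard_labels) for p in subset]
                    )
                )
            else:
                s = float(_aligned_accuracy(result.hard_labels, reference))
            names = tuple(method_pool[i].name for i in combo)
            scores[names] = s
            key = (-s, len(names), names)
            if best is None or key < best[0]:
                best = (key, tuple(method_pool[i] for i in combo))
    return best[1], scores
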