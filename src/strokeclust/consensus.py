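"""Consensus combination by symmetric nonnegative matrix tri-factorization.

The co-association matrix CM is factorized as CM ~ N L N^T with N (n x k)
a soft cluster-assignment factor and L (k x k) a cluster-interaction
factor, both nonnegative, by alternating multiplicative updates:

    N <- N * (CM N L) / (N N^T CM N L + eps)
    L <- L * (N^T CM N) / (N^T N L N^T N + eps)

``update_step`` applies these ratio updates with a configurable exponent.
Exponent 1 is the plain ratio rule; exponent 0.5 (the default used by the
fitter) multiplies by the square root of the ratio instead.  Both share
exactly the same fixed points — any (N, L) where the ratios are 1 is
stationary under either — but the plain rule can overshoot and transiently
increase the objective on unstructured matrices, while the damped rule
behaves as a reliably monotone descent in practice.  Hard consensus labels
are the row-wise argmax of N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import ConfigurationError, InputError, NumericError
from .base_clustering import ConsensusMatrix
from .preprocess import FeatureMatrix


@dataclass(frozen=True)
class MNMFConfig:
    """Settings for the tri-factor consensus fit.

    ``n_restarts`` seeded restarts are run and the lowest final objective
    kept; 100 restarts is the variance-reduction protocol used at study
    scale.  ``damping`` is the exponent applied to the multiplicative
    update ratios (0.5 = square-root damped, 1.0 = plain rule).
    """

    k: int
    max_iter: int = 500
    tol: float = 1e-6
    eps: float = 1e-10
    seed: int = 0
    n_restarts: int = 100
    damping: float = 0.5

    def validate(self) -> None:
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        if self.tol <= 0 or self.eps <= 0:
            raise ConfigurationError("tol and eps must be > 0")
        if self.n_restarts < 1:
            raise ConfigurationError("n_restarts must be >= 1")
        if not 0 < self.damping <= 1:
            raise ConfigurationError("damping must lie in (0, 1]")


@dataclass(frozen=True)
class MNMFResult:
    N: np.ndarray
    L: np.ndarray
    objective_trace: np.ndarray
    hard_labels: np.ndarray
    converged: bool
    restart_objectives: np.ndarray
    orthogonality_gap: float


@dataclass(frozen=True)
class ClusterCenters:
    """Feature-space cluster centers: row c = mean of rows with hard label c."""

    centers: np.ndarray
    counts: np.ndarray


def _as_cm(cm) -> np.ndarray:
    return cm.values if isinstance(cm, ConsensusMatrix) else np.asarray(cm, float)


def reconstruction_error(CM, N, L) -> float:
    """Squared Frobenius objective ||CM - N L N^T||^2."""
    R = _as_cm(CM) - N @ L @ N.T
    return float((R * R).sum())


def initialize_factors(cm, config: MNMFConfig, seed: int | None = None):
    """Strictly positive seeded initialization.

    N starts from the indicator matrix of a k-means partition of CM's rows
    plus a uniform 0.2 offset (the offset keeps every entry positive, so no
    entry is permanently zero-locked by the multiplicative updates); L is
    the projected interaction N^T CM N normalized by the column-sum outer
    product.
    """
    CM = _as_cm(cm)
    n = CM.shape[0]
    if config.k > n:
        raise ConfigurationError(f"k={config.k} exceeds n={n}")
    rs = config.seed if seed is None else seed
    km = KMeans(n_clusters=config.k, n_init=1, init="random", random_state=rs).fit(CM)
    N = np.full((n, config.k), 0.2)
    N[np.arange(n), km.labels_] += 1.0
    c = N.sum(axis=0)
    L = (N.T @ CM @ N) / np.outer(c, c)
    return N, L


def update_step(CM, N, L, eps: float = 1e-10, exponent: float = 1.0):
    """One alternating multiplicative update of (N, L).

    Applies the N ratio update first, then the L update using the updated
    N.  ``exponent`` < 1 damps each step by raising the ratio to that
    power; fixed points are unchanged.  Nonnegativity is preserved by
    construction.
    """
    CM = _as_cm(CM)
    ratio_n = (CM @ N @ L) / (N @ (N.T @ CM @ N @ L) + eps)
    N = N * ratio_n**exponent if exponent != 1.0 else N * ratio_n
    G = N.T @ N
    ratio_l = (N.T @ CM @ N) / (G @ L @ G + eps)
    L = L * ratio_l**exponent if exponent != 1.0 else L * ratio_l
    if not (np.all(np.isfinite(N)) and np.all(np.isfinite(L))):
        raise NumericError("non-finite factor entries after update")
    return N, L


def _repair_empty_clusters(N: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Give each empty cluster the point with the weakest assignment margin."""
    labels = labels.copy()
    for c in range(k):
        if np.any(labels == c):
            continue
        top = N[np.arange(len(labels)), labels]
        masked = N.copy()
        masked[np.arange(len(labels)), labels] = -np.inf
        margin = top - masked.max(axis=1)
        counts = np.bincount(labels, minlength=k)
        movable = counts[labels] >= 2
        if not movable.any():
            raise NumericError("cannot repair empty cluster: no movable points")
        margin[~movable] = np.inf
        labels[int(np.argmin(margin))] = c
    return labels


def mnmf_fit(cm, features, config: MNMFConfig):
    """Fit the tri-factor consensus model with seeded restarts.

    Each restart iterates :func:`update_step` (with the configured damping
    exponent) until the relative objective change drops below ``tol`` or
    ``max_iter`` is reached; the restart with the lowest final objective is
    kept.  Hard labels are the row argmax of N (ties -> lowest index);
    empty clusters are repaired by reassigning the weakest-margin points.
    Returns ``(MNMFResult, ClusterCenters)``; centers are feature-space
    means of the hard clusters (``None`` when ``features`` is ``None``).
    """
    config.validate()
    CM = _as_cm(cm)
    n = CM.shape[0]
    X = None
    if features is not None:
        X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
        if X.shape[0] != n:
            raise InputError("features and consensus matrix cover different n")

    best = None
    finals = np.empty(config.n_restarts)
    for r in range(config.n_restarts):
        rs = (config.seed + r) % 2**31
        N, L = initialize_factors(CM, config, seed=rs)
        trace = [reconstruction_error(CM, N, L)]
        converged = False
        for it in range(config.max_iter):
            # safeguarded step: the multiplicative ratio raised to a small
            # enough power is always a descent step away from stationary
            # points, so halve the exponent until the objective does not rise
            exponent = config.damping
            while True:
                try:
                    N_c, L_c = update_step(CM, N, L, eps=config.eps, exponent=exponent)
                except NumericError as err:
                    raise NumericError(f"restart {r}, iteration {it}: {err}") from err
                obj = reconstruction_error(CM, N_c, L_c)
                if obj <= trace[-1] or exponent < 1e-4:
                    break
                exponent /= 2.0
            if obj > trace[-1]:  # no descent found: stationary point
                converged = True
                break
            N, L = N_c, L_c
            trace.append(obj)
            if abs(trace[-2] - obj) <= config.tol * max(trace[-2], config.eps):
                converged = True
                break
        finals[r] = trace[-1]
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], N, L, np.array(trace), converged)

    _, N, L, trace, converged = best
    labels = np.argmax(N, axis=1)
    labels = _repair_empty_clusters(N, labels, config.k)
    gap = float(np.linalg.norm(N.T @ N - np.eye(config.k)))
    result = MNMFResult(
        N=N,
        L=L,
        objective_trace=trace,
        hard_labels=labels,
        converged=converged,
        restart_objectives=finals,
        orthogonality_gap=gap,
    )
    centers = None
    if X is not None:
        counts = np.bincount(labels, minlength=config.k)
        means = np.vstack(
            [
                X[labels == c].mean(axis=0) if counts[c] else np.zeros(X.shape[1])
                for c in range(config.k)
            ]
        )
        centers = ClusterCenters(centers=means, counts=counts)
    return result, centers
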