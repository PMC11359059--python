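"""Horizontal federation of the consensus-clustering pipeline.

Subjects are partitioned across clients; each client runs the full local
pipeline (eight-method ensemble -> co-association matrix -> tri-factor NMF
consensus) and ships only a summary — cluster centers, per-cluster mean
trunk displacement, severity ranks, local labels and its wall time — to the
server.  The server aligns clusters across clients by severity rank (rank
0 = lowest trunk displacement = mildest everywhere) and aggregates centers
with FedAvg: a single data-size-weighted average over participating
clients.  Raw feature rows never cross the client boundary.

A one-client federation is exactly the centralized pipeline: the partition
keeps rows in canonical order and clients share one pipeline configuration,
so ``run_centralized`` and an M=1 ``run_federated`` are bit-identical.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, InputError
from .base_clustering import MethodSpec, consensus_matrix, default_method_specs, run_method
from .consensus import MNMFConfig, mnmf_fit
from .evaluation import TimingReport, severity_level_names, timing
from .preprocess import FeatureMatrix


@dataclass(frozen=True)
class PipelineConfig:
    """The local pipeline every client runs, shared verbatim across clients."""

    k: int
    method_specs: tuple[MethodSpec, ...]
    mnmf: MNMFConfig

    def validate(self) -> None:
        if self.mnmf.k != self.k:
            raise ConfigurationError("pipeline k and MNMF k must agree")
        self.mnmf.validate()


def default_pipeline(k: int, seed: int = 0, n_restarts: int = 20) -> PipelineConfig:
    return PipelineConfig(
        k=k,
        method_specs=default_method_specs(seed),
        mnmf=MNMFConfig(k=k, seed=seed, n_restarts=n_restarts),
    )


@dataclass(frozen=True)
class FederationConfig:
    n_clients: int
    k: int
    pipeline: PipelineConfig
    partition_seed: int = 0
    participating: tuple[int, ...] | None = None  # default: all clients

    def validate(self) -> None:
        if self.n_clients < 1:
            raise ConfigurationError("n_clients must be >= 1")
        if self.k != self.pipeline.k:
            raise ConfigurationError("federation k and pipeline k must agree")
        self.pipeline.validate()


@dataclass(frozen=True)
class ClientData:
    """One client's private shard; never leaves the client boundary."""

    client_id: int
    row_ids: tuple[str, ...]
    features: np.ndarray
    trunk_td: np.ndarray


@dataclass(frozen=True)
class ClientSummary:
    """Everything a client transmits to the server — no raw feature rows."""

    client_id: int
    n_points: int
    centers: np.ndarray
    cluster_td: np.ndarray
    severity_rank: np.ndarray
    local_labels: np.ndarray
    row_ids: tuple[str, ...]
    comp_time_s: float


@dataclass(frozen=True)
class GlobalModel:
    """FedAvg-aggregated global centers, ordered mildest -> most severe."""

    W: np.ndarray
    severity_label_per_cluster: tuple[str, ...]
    weights_used: dict
    comm_time_s: float


def partition_clients(
    features: FeatureMatrix, trunk_td: pd.Series, config: FederationConfig
) -> list[ClientData]:
    """Seeded uniform random split of subjects into disjoint client shards.

    Shard sizes differ by at most one; each client keeps its rows in the
    canonical (feature-matrix) order, so a one-client partition reproduces
    the full matrix exactly.
    """
    config.validate()
    n = features.n
    if n < config.n_clients * config.k:
        raise ConfigurationError(
            f"n={n} subjects cannot give every one of {config.n_clients} clients"
            f" at least k={config.k}"
        )
    td = trunk_td.reindex(list(features.row_ids))
    if td.isna().any():
        raise InputError("trunk displacement missing for some subjects")
    rng = np.random.default_rng(config.partition_seed)
    perm = rng.permutation(n)
    shards = np.array_split(perm, config.n_clients)
    clients = []
    for cid, idx in enumerate(shards):
        idx = np.sort(idx)
        clients.append(
            ClientData(
                client_id=cid,
                row_ids=tuple(features.row_ids[i] for i in idx),
                features=features.values[idx],
                trunk_td=td.to_numpy()[idx],
            )
        )
    return clients


def run_client(client: ClientData, pipeline: PipelineConfig) -> ClientSummary:
    """Run the full local pipeline on one client's shard.

    Pure function of (shard, pipeline): identical inputs give identical
    summaries (apart from the measured wall time).  Severity ranks are
    assigned by ascending per-cluster mean trunk displacement.
    """
    t0 = time.perf_counter()
    partitions = [
        run_method(client.features, spec, pipeline.k) for spec in pipeline.method_specs
    ]
    cm = consensus_matrix(partitions)
    result, centers = mnmf_fit(cm, client.features, pipeline.mnmf)
    labels = result.hard_labels
    cluster_td = np.array(
        [client.trunk_td[labels == c].mean() for c in range(pipeline.k)]
    )
    order = np.argsort(cluster_td, kind="stable")
    rank = np.empty(pipeline.k, dtype=int)
    rank[order] = np.arange(pipeline.k)
    return ClientSummary(
        client_id=client.client_id,
        n_points=len(labels),
        centers=centers.centers,
        cluster_td=cluster_td,
        severity_rank=rank,
        local_labels=labels,
        row_ids=client.row_ids,
        comp_time_s=time.perf_counter() - t0,
    )


def fedavg(summaries: list[ClientSummary], config: FederationConfig) -> GlobalModel:
    """Aggregate client centers into global centers by weighted averaging.

    Clusters are aligned across clients by severity rank — rank r on every
    client maps to global cluster r — then W_r is the client-size-weighted
    mean of the aligned centers.  Summaries are processed in client-id
    order, so the result is independent of the order they arrive in.
    """
    t0 = time.perf_counter()
    if not summaries:
        raise InputError("need at least one client summary")
    if config.participating is not None:
        summaries = [s for s in summaries if s.client_id in config.participating]
        if not summaries:
            raise InputError("no participating client summaries")
    summaries = sorted(summaries, key=lambda s: s.client_id)
    k, d = summaries[0].centers.shape
    if k != config.k or any(s.centers.shape != (k, d) for s in summaries):
        raise InputError("client summaries disagree on k or feature dimension")
    n_total = sum(s.n_points for s in summaries)
    W = np.zeros((k, d))
    weights = {}
    for s in summaries:
        w = s.n_points / n_total
        weights[s.client_id] = w
        inv = np.argsort(s.severity_rank, kind="stable")  # cluster index per rank
        W += w * s.centers[inv]
    return GlobalModel(
        W=W,
        severity_label_per_cluster=severity_level_names(k),
        weights_used=weights,
        comm_time_s=time.perf_counter() - t0,
    )


def assign_global(features: FeatureMatrix | np.ndarray, model: GlobalModel) -> np.ndarray:
    """Label each subject with its nearest global center (severity index).

    Euclidean nearest center; exact ties resolve toward the milder cluster
    (lower index, since W rows are ordered mildest first).
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if X.shape[1] != model.W.shape[1]:
        raise InputError("feature dimension does not match the global model")
    return np.argmin(cdist(X, model.W, "euclidean"), axis=1)


@dataclass(frozen=True)
class FederatedRun:
    model: GlobalModel
    labels: np.ndarray
    summaries: list[ClientSummary]
    timing: TimingReport


def run_federated(
    features: FeatureMatrix, trunk_td: pd.Series, config: FederationConfig
) -> FederatedRun:
    """End-to-end federated run: partition, local pipelines, FedAvg, labeling."""
    clients = partition_clients(features, trunk_td, config)
    summaries = [run_client(c, config.pipeline) for c in clients]
    model = fedavg(summaries, config)
    labels = assign_global(features, model)
    return FederatedRun(
        model=model,
        labels=labels,
        summaries=summaries,
        timing=timing(summaries, model.comm_time_s),
    )


def run_centralized(
    features: FeatureMatrix, trunk_td: pd.Series, pipeline: PipelineConfig
) -> FederatedRun:
    """Centralized reference: the identical pipeline on one all-data client."""
    config = FederationConfig(n_clients=1, k=pipeline.k, pipeline=pipeline)
    return run_federated(features, trunk_td, config)
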