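"""Client partitioning, local pipelines, FedAvg aggregation, global labels."""

import dataclasses

import numpy as np
import pytest

from strokeclust import (
    ClientData,
    ClientSummary,
    ConfigurationError,
    FederationConfig,
    GlobalModel,
    InputError,
    assign_global,
    default_pipeline,
    fedavg,
    partition_clients,
    run_client,
    run_federated,
)
from strokeclust.evaluation import severity_level_names


def _config(n_clients, k=3, seed=0, n_restarts=3):
    return FederationConfig(
        n_clients=n_clients,
        k=k,
        pipeline=default_pipeline(k, seed=seed, n_restarts=n_restarts),
        partition_seed=seed,
    )


def _summary(cid, n, centers, td=None):
    centers = np.asarray(centers, float)
    k = centers.shape[0]
    td = np.arange(k, dtype=float) if td is None else np.asarray(td, float)
    order = np.argsort(td, kind="stable")
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    return ClientSummary(
        client_id=cid,
        n_points=n,
        centers=centers,
        cluster_td=td,
        severity_rank=rank,
        local_labels=np.zeros(n, dtype=int),
        row_ids=tuple(f"r{cid}_{i}" for i in range(n)),
        comp_time_s=0.0,
    )


class TestPartition:
    def test_thirty_subjects_fifteen_clients(self, tiny_features):
        fm, td, _ = tiny_features  # 12 subjects
        config = _config(6, k=2)
        clients = partition_clients(fm, td, config)
        assert len(clients) == 6
        sizes = [len(c.row_ids) for c in clients]
        assert all(s == 2 for s in sizes)
        all_ids = [rid for c in clients for rid in c.row_ids]
        assert sorted(all_ids) == sorted(fm.row_ids)
        assert len(set(all_ids)) == fm.n

    def test_single_client_holds_everything_in_canonical_order(self, tiny_features):
        fm, td, _ = tiny_features
        (client,) = partition_clients(fm, td, _config(1))
        assert client.row_ids == fm.row_ids
        np.testing.assert_array_equal(client.features, fm.values)

    def test_seeded_determinism(self, tiny_features):
        fm, td, _ = tiny_features
        a = partition_clients(fm, td, _config(3))
        b = partition_clients(fm, td, _config(3))
        assert [c.row_ids for c in a] == [c.row_ids for c in b]

    def test_too_many_clients_rejected(self, tiny_features):
        fm, td, _ = tiny_features
        with pytest.raises(ConfigurationError):
            partition_clients(fm, td, _config(5, k=3))  # 12 < 5*3


class TestRunClient:
    def test_identical_shards_give_identical_summaries(self, tiny_features):
        fm, td, _ = tiny_features
        (client,) = partition_clients(fm, td, _config(1))
        twin = dataclasses.replace(client, client_id=99)
        pipeline = _config(1).pipeline
        a = run_client(client, pipeline)
        b = run_client(twin, pipeline)
        np.testing.assert_array_equal(a.centers, b.centers)
        np.testing.assert_array_equal(a.local_labels, b.local_labels)
        np.testing.assert_array_equal(a.severity_rank, b.severity_rank)
        assert b.client_id == 99

    def test_severity_rank_orders_by_ascending_trunk_displacement(self, tiny_features):
        fm, td, groups = tiny_features
        (client,) = partition_clients(fm, td, _config(1))
        summary = run_client(client, _config(1).pipeline)
        ranked_td = summary.cluster_td[np.argsort(summary.severity_rank, kind="stable")]
        assert np.all(np.diff(ranked_td) >= 0)

    def test_summary_shares_no_raw_feature_rows(self, tiny_features):
        fm, td, _ = tiny_features
        (client,) = partition_clients(fm, td, _config(1))
        summary = run_client(client, _config(1).pipeline)
        fields = {f.name for f in dataclasses.fields(ClientSummary)}
        assert fields == {
            "client_id",
            "n_points",
            "centers",
            "cluster_td",
            "severity_rank",
            "local_labels",
            "row_ids",
            "comp_time_s",
        }
        # the only matrix transmitted is k x d, never n_points x d
        assert summary.centers.shape[0] == _config(1).k < summary.n_points


class TestFedAvg:
    def test_hand_computed_weighted_mean(self):
        model = fedavg(
            [_summary(0, 2, [[0.0], [5.0]]), _summary(1, 6, [[2.0], [7.0]])],
            _config(2, k=2),
        )
        np.testing.assert_allclose(model.W, [[1.5], [6.5]])
        assert model.weights_used == {0: 0.25, 1: 0.75}

    def test_single_client_identity(self):
        centers = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        model = fedavg([_summary(0, 7, centers)], _config(1))
        np.testing.assert_array_equal(model.W, centers)

    def test_identical_centers_unmoved_by_weights(self):
        c = [[1.0], [2.0]]
        model = fedavg(
            [_summary(0, 3, c), _summary(1, 30, c), _summary(2, 1, c)],
            _config(3, k=2),
        )
        np.testing.assert_allclose(model.W, c)

    def test_alignment_uses_severity_rank_not_cluster_index(self):
        # client 1 stores its mildest cluster at index 1
        a = _summary(0, 4, [[0.0], [10.0]], td=[1.0, 5.0])
        b = _summary(1, 4, [[9.0], [1.0]], td=[5.0, 1.0])
        model = fedavg([a, b], _config(2, k=2))
        np.testing.assert_allclose(model.W, [[0.5], [9.5]])

    def test_client_order_permutation_exactly_invariant(self):
        rng = np.random.default_rng(8)
        summaries = [
            _summary(i, int(rng.integers(2, 9)), rng.normal(size=(3, 4))) for i in range(5)
        ]
        a = fedavg(summaries, _config(5))
        b = fedavg(summaries[::-1], _config(5))
        np.testing.assert_array_equal(a.W, b.W)
        assert a.weights_used == b.weights_used

    def test_weights_sum_to_one(self):
        summaries = [_summary(i, n, np.zeros((2, 2))) for i, n in enumerate([3, 5, 9])]
        model = fedavg(summaries, _config(3, k=2))
        assert sum(model.weights_used.values()) == pytest.approx(1.0, abs=1e-12)

    def test_mismatched_dimensions_rejected(self):
        with pytest.raises(InputError):
            fedavg(
                [_summary(0, 2, np.zeros((2, 2))), _summary(1, 2, np.zeros((2, 3)))],
                _config(2, k=2),
            )


class TestAssignGlobal:
    def _model(self, W):
        W = np.asarray(W, float)
        return GlobalModel(
            W=W,
            severity_label_per_cluster=severity_level_names(W.shape[0]),
            weights_used={0: 1.0},
            comm_time_s=0.0,
        )

    def test_point_at_center_gets_its_label(self):
        model = self._model([[0.0, 0.0], [4.0, 4.0]])
        labels = assign_global(np.array([[4.0, 4.0], [0.0, 0.0]]), model)
        assert labels.tolist() == [1, 0]

    def test_equidistant_point_goes_to_milder_cluster(self):
        model = self._model([[0.0], [2.0]])
        assert assign_global(np.array([[1.0]]), model).tolist() == [0]

    def test_separated_groups_fully_recovered(self, rng):
        W = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        pts = np.vstack([W[c] + rng.normal(0, 0.5, size=(20, 2)) for c in range(3)])
        labels = assign_global(pts, self._model(W))
        assert labels.tolist() == np.repeat([0, 1, 2], 20).tolist()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InputError):
            assign_global(np.zeros((3, 4)), self._model([[0.0], [1.0]]))


def test_degenerate_federation_matches_explicit_centralized_pipeline(tiny_features):
    """An M=1 federated run must equal composing the stages by hand."""
    from strokeclust import consensus_matrix, mnmf_fit, run_method

    fm, td, _ = tiny_features
    config = _config(1, k=3, seed=5)
    run = run_federated(fm, td, config)

    parts = [run_method(fm, s, 3) for s in config.pipeline.method_specs]
    result, centers = mnmf_fit(consensus_matrix(parts), fm, config.pipeline.mnmf)
    cluster_td = np.array(
        [td.to_numpy()[result.hard_labels == c].mean() for c in range(3)]
    )
    order = np.argsort(cluster_td, kind="stable")
    np.testing.assert_array_equal(run.model.W, centers.centers[order])
    assert run.timing.total_s == run.timing.comp_time_s + run.timing.comm_time_s
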