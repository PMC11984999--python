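"""Federated averaging: merge oracle, round orchestration, equivalences."""

import warnings

import numpy as np
import pytest

from fedmammo import (
    ClientData,
    FLConfig,
    TrainConfig,
    build_model,
    fedavg_merge,
    rounds_epochs_sweep,
    run_federated,
    train_centralized,
)


def toy_clients(rng, n_clients=2, n=20, size=16):
    clients = {}
    for c in range(n_clients):
        X = rng.random((n, size, size)).astype(np.float32) * 0.1
        y = rng.integers(0, 2, n)
        X[y == 1, 4:12, 4:12] += 0.8
        clients[f"c{c}"] = ClientData(train=(X, y), val=(X[:4], y[:4]))
    Xt = rng.random((10, size, size)).astype(np.float32) * 0.1
    yt = rng.integers(0, 2, 10)
    Xt[yt == 1, 4:12, 4:12] += 0.8
    return clients, {"test": (Xt, yt)}


def small_cfg(rounds, epochs, seed=0, lr=1e-3):
    return FLConfig(
        rounds=rounds, local_epochs=epochs, seed=seed,
        client_config=TrainConfig(learning_rate=lr, batch_size=10, epochs=1, seed=seed),
    )


def builder16(seed):
    return build_model(n_classes=2, input_size=(16, 16), seed=seed)


class TestFedavgMerge:
    def test_matches_weighted_mean_oracle(self, rng):
        """Independent per-parameter oracle: explicit sum of weight*param."""
        models = [builder16(s) for s in range(3)]
        states = [m.state_dict() for m in models]
        counts = [10, 30, 60]
        merged = fedavg_merge(states, counts, "sample_size")
        w = np.array(counts) / 100
        for k in states[0]:
            oracle = sum(wi * s[k].astype(np.float64) for wi, s in zip(w, states))
            assert np.allclose(merged[k], oracle, atol=1e-7)

    def test_uniform_weighting_oracle(self):
        states = [m.state_dict() for m in (builder16(0), builder16(1))]
        merged = fedavg_merge(states, weighting="uniform")
        for k in states[0]:
            oracle = (states[0][k].astype(np.float64) + states[1][k]) / 2
            assert np.allclose(merged[k], oracle, atol=1e-7)

    def test_identical_models_fixed_point_exact(self):
        state = builder16(7).state_dict()
        copies = [{k: v.copy() for k, v in state.items()} for _ in range(3)]
        for weighting, counts in (("uniform", None), ("sample_size", [1, 5, 7])):
            merged = fedavg_merge(copies, counts, weighting)
            assert all(np.array_equal(merged[k], state[k]) for k in state)

    def test_two_scalar_parameters(self):
        a = {"p": np.array([2.0])}
        b = {"p": np.array([4.0])}
        assert fedavg_merge([a, b], weighting="uniform")["p"][0] == pytest.approx(3.0)
        got = fedavg_merge([a, b], [100, 300], "sample_size")["p"][0]
        assert got == pytest.approx(0.25 * 2 + 0.75 * 4)  # = 3.5

    def test_architecture_mismatch_rejected(self):
        a = {"p": np.zeros(3)}
        b = {"q": np.zeros(3)}
        with pytest.raises(ValueError, match="architecture"):
            fedavg_merge([a, b], weighting="uniform")
        c = {"p": np.zeros(4)}
        with pytest.raises(ValueError, match="architecture"):
            fedavg_merge([a, c], weighting="uniform")


class TestRunFederated:
    def test_epoch_bookkeeping_and_history_length(self, rng):
        clients, tests = toy_clients(rng)
        result = run_federated(clients, tests, small_cfg(4, 3), builder16)
        assert len(result.rounds) == 4
        assert all(n == 12 for n in result.client_epochs.values())

    def test_empty_client_rejected_before_round_one(self, rng):
        clients, tests = toy_clients(rng)
        clients["empty"] = ClientData(
            train=(np.zeros((0, 16, 16), np.float32), np.array([], int)),
            val=clients["c0"].val,
        )
        with pytest.raises(ValueError, match="empty"):
            run_federated(clients, tests, small_cfg(1, 1), builder16)

    def test_single_client_equals_centralized_bitwise(self, rng):
        """Federated averaging over one client is the identity, so R rounds of
        E local epochs must reproduce centralized R*E-epoch training exactly."""
        clients, tests = toy_clients(rng, n_clients=1)
        X, y = clients["c0"].train
        Xv, yv = clients["c0"].val

        fed = run_federated(clients, tests, small_cfg(5, 2, seed=4), builder16)

        model = builder16(4)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=10, epochs=10, seed=4)
        train_centralized(model, (X, y), (Xv, yv), cfg)

        fed_state = fed.model.state_dict()
        cen_state = model.state_dict()
        assert all(np.array_equal(fed_state[k], cen_state[k]) for k in cen_state)

    def test_round_records_carry_losses_and_f1(self, rng):
        clients, tests = toy_clients(rng)
        result = run_federated(clients, tests, small_cfg(2, 1), builder16)
        rec = result.rounds[0]
        assert set(rec.client_losses) == {"c0", "c1"}
        assert set(rec.test_f1) == {"test"}


class TestHeterogeneityWarning:
    def test_homogeneous_cohort_warns(self):
        import pandas as pd

        from fedmammo.federated import _warn_if_homogeneous
        from fedmammo.types import DicomMeta, ImageRecord

        records = [
            ImageRecord(pixels=np.full((8, 8), v, dtype=np.uint16), meta=DicomMeta())
            for v in (100, 2000, 105, 2010)  # near-identical hospital ranges
        ]
        manifest = pd.DataFrame(
            {"hospital_id": ["A", "A", "B", "B"], "record_index": range(4)}
        )
        with pytest.warns(UserWarning, match="not heterogeneous"):
            _warn_if_homogeneous(manifest, records)

    def test_disjoint_ranges_do_not_warn(self):
        import pandas as pd

        from fedmammo.federated import _warn_if_homogeneous
        from fedmammo.types import DicomMeta, ImageRecord

        records = [
            ImageRecord(pixels=np.full((8, 8), v, dtype=np.uint16), meta=DicomMeta())
            for v in (100, 200, 3000, 4000)
        ]
        manifest = pd.DataFrame(
            {"hospital_id": ["A", "A", "B", "B"], "record_index": range(4)}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            _warn_if_homogeneous(manifest, records)


class TestRoundsEpochsSweep:
    def test_one_row_per_combo_and_common_start(self, rng):
        clients, tests = toy_clients(rng)
        table, traces = rounds_epochs_sweep(
            clients, tests, [(4, 1), (2, 2), (1, 4)], small_cfg(1, 1), builder16
        )
        assert len(table) == 3
        assert (table.total_epochs == 4).all()
        assert set(traces) == {(4, 1), (2, 2), (1, 4)}
        assert [len(traces[k]) for k in [(4, 1), (2, 2), (1, 4)]] == [4, 2, 1]

    def test_unequal_total_epochs_warns(self, rng):
        clients, tests = toy_clients(rng)
        with pytest.warns(UserWarning, match="total local epochs"):
            rounds_epochs_sweep(
                clients, tests, [(2, 1), (2, 2)], small_cfg(1, 1), builder16
            )

    def test_equal_total_epochs_do_not_warn(self, rng):
        clients, tests = toy_clients(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            rounds_epochs_sweep(clients, tests, [(2, 2), (4, 1)], small_cfg(1, 1), builder16)
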