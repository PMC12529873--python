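"""Aggregation operators, round loop, protocol equivalences, privacy contract."""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
import pytest

from fedspine.federated import (
    AggregationError,
    Client,
    ClientUpdate,
    FLSchedule,
    ServerState,
    fedavg_aggregate,
    fedopt_server_step,
    fedprox_client_objective,
    run_fl,
    run_round,
)
from fedspine.model import HourglassNet
from fedspine.nn import ParamVector
from fedspine.synthetic import SpineSample, samples_in_split
from fedspine.training import TrainConfig, fit
from fedspine.utils import derive_seed


def pv(**arrays) -> ParamVector:
    return ParamVector(OrderedDict((k, np.asarray(v, dtype=float)) for k, v in arrays.items()))


def update(cid, n, **arrays) -> ClientUpdate:
    return ClientUpdate(params=pv(**arrays), n_samples=n, client_id=cid)


class TestFedAvg:
    def test_identical_clients_return_their_params(self):
        u1 = update("a", 3, w=[[1.0, 2.0]], b=[0.5])
        u2 = update("b", 9, w=[[1.0, 2.0]], b=[0.5])
        agg = fedavg_aggregate([u1, u2])
        assert np.array_equal(agg["w"], [[1.0, 2.0]])
        assert np.array_equal(agg["b"], [0.5])

    def test_weighted_scalar_mean(self):
        agg = fedavg_aggregate([update("a", 3, w=[0.0]), update("b", 1, w=[1.0])])
        assert agg["w"] == pytest.approx([0.25])

    def test_single_client_passthrough(self):
        u = update("a", 5, w=[1.5, -2.0])
        assert np.array_equal(fedavg_aggregate([u])["w"], u.params["w"])

    def test_empty_list_rejected(self):
        with pytest.raises(AggregationError):
            fedavg_aggregate([])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(AggregationError):
            fedavg_aggregate([update("a", 1, w=[1.0]), update("b", 1, w=[1.0, 2.0])])

    def test_nonpositive_count_rejected(self):
        with pytest.raises(AggregationError):
            update("a", 0, w=[1.0])

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(0)
        updates = [
            update(f"c{i}", int(rng.integers(1, 40)),
                   w=rng.normal(size=(3, 4)), b=rng.normal(size=5))
            for i in range(6)
        ]
        agg = fedavg_aggregate(updates)
        total = sum(u.n_samples for u in updates)
        for key in ("w", "b"):
            brute = np.zeros_like(updates[0].params[key])
            it = np.nditer(brute, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                brute[idx] = sum(
                    u.n_samples / total * u.params[key][idx] for u in updates
                )
            assert agg[key] == pytest.approx(brute, abs=1e-12)

    def test_permutation_invariant_bitwise(self):
        rng = np.random.default_rng(1)
        updates = [
            update(f"c{i}", int(rng.integers(1, 9)), w=rng.normal(size=(2, 2)))
            for i in range(5)
        ]
        a = fedavg_aggregate(updates)
        b = fedavg_aggregate(list(reversed(updates)))
        assert a.equal(b)


class TestFedOpt:
    def test_fixed_point_when_clients_return_global(self):
        g = pv(w=[1.0, -2.0])
        state = ServerState(global_params=g.copy())
        ups = [update("a", 2, w=[1.0, -2.0]), update("b", 3, w=[1.0, -2.0])]
        sch = FLSchedule.default("fedopt")
        new = fedopt_server_step(state, ups, sch)
        assert new.global_params["w"] == pytest.approx(g["w"], abs=1e-12)
        assert new.round_index == 1

    def test_plain_mode_with_unit_lr_reduces_to_fedavg(self):
        state = ServerState(global_params=pv(w=[5.0, 5.0]))
        ups = [update("a", 3, w=[0.0, 1.0]), update("b", 1, w=[1.0, 3.0])]
        sch = FLSchedule("fedopt", 1, 1, 1e-3, server_lr=1.0, fedopt_plain=True)
        new = fedopt_server_step(state, ups, sch)
        assert new.global_params.equal(fedavg_aggregate(ups))

    def test_scalar_adaptive_step_matches_hand_arithmetic(self):
        theta, avg, lr, tau = 2.0, 1.0, 0.1, 1e-9
        b1, b2 = 0.9, 0.999
        state = ServerState(global_params=pv(w=[theta]))
        sch = FLSchedule("fedopt", 1, 1, 1e-3, server_lr=lr,
                         server_betas=(b1, b2), server_tau=tau)
        new = fedopt_server_step(state, [update("a", 1, w=[avg])], sch)
        g = theta - avg
        m = (1 - b1) * g
        v = (1 - b2) * g * g
        want = theta - lr * m / (np.sqrt(v) + tau)
        assert new.global_params["w"][0] == pytest.approx(want, abs=1e-12)
        # second round with the same update: moments accumulate
        new2 = fedopt_server_step(new, [update("a", 1, w=[avg])], sch)
        g2 = new.global_params["w"][0] - avg
        m2 = b1 * m + (1 - b1) * g2
        v2 = b2 * v + (1 - b2) * g2 * g2
        want2 = new.global_params["w"][0] - lr * m2 / (np.sqrt(v2) + tau)
        assert new2.global_params["w"][0] == pytest.approx(want2, abs=1e-12)


class TestFedProxObjective:
    def test_mu_zero_equals_base_loss(self):
        base = lambda p: 3.5
        assert fedprox_client_objective(base, pv(w=[1.0]), pv(w=[9.0]), 0.0) == 3.5

    def test_zero_penalty_at_global(self):
        base = lambda p: 1.0
        g = pv(w=[2.0, 3.0])
        assert fedprox_client_objective(base, g, g, 5.0) == pytest.approx(1.0)

    def test_penalty_arithmetic(self):
        base = lambda p: 0.0
        p = pv(w=[2.0])
        g = pv(w=[0.0])  # ||delta||^2 = 4
        assert fedprox_client_objective(base, p, g, 2.0) == pytest.approx(4.0)


@pytest.fixture(scope="module")
def fl_setup(small_cohort, small_split, tiny_model_cfg):
    centers = sorted({s.center_id for s in small_cohort})
    train_by_center = {
        c: samples_in_split(small_cohort, small_split, "train", center=c)
        for c in centers
    }
    val = samples_in_split(small_cohort, small_split, "validation")
    return train_by_center, val


class TestRoundLoop:
    def test_single_client_round_equals_local_epochs(self, fl_setup, tiny_model_cfg):
        """One-client FedAvg follows the plain local trajectory bit-for-bit."""
        train_by_center, _ = fl_setup
        center = sorted(train_by_center)[0]
        samples = train_by_center[center]
        net = HourglassNet(tiny_model_cfg)
        init = net.init_params(3)

        sch = FLSchedule("fedavg", local_epochs=2, rounds=1, client_lr=1e-3)
        fed_params, _, _ = run_fl(
            {center: samples}, [], sch, tiny_model_cfg, rng_seed=17, init_params=init
        )

        tcfg = TrainConfig(
            epochs=2, lr=1e-3, batch_size=8, augment=False,
            seed=derive_seed(17, 0),  # the seed run_fl derives for client 0
            lr_decay_after=50,
        )
        # "always improving" metric makes checkpointing keep the final epoch
        local = fit(
            samples, samples, tiny_model_cfg, tcfg, init_params=init,
            val_metric_fn=lambda net_, p_, e_: -float(e_),
        )
        assert fed_params.equal(local.best_params)

    def test_same_seed_bit_identical(self, fl_setup, tiny_model_cfg):
        train_by_center, val = fl_setup
        sch = FLSchedule("fedavg", local_epochs=1, rounds=2, client_lr=1e-3)
        a, ha, _ = run_fl(train_by_center, val, sch, tiny_model_cfg, rng_seed=5)
        b, hb, _ = run_fl(train_by_center, val, sch, tiny_model_cfg, rng_seed=5)
        assert a.equal(b)
        assert [h["val_metric"] for h in ha] == [h["val_metric"] for h in hb]

    def test_zero_rounds_returns_initial_params(self, fl_setup, tiny_model_cfg):
        train_by_center, val = fl_setup
        net = HourglassNet(tiny_model_cfg)
        init = net.init_params(1)
        sch = FLSchedule("fedavg", local_epochs=1, rounds=0, client_lr=1e-3)
        params, history, _ = run_fl(
            train_by_center, val, sch, tiny_model_cfg, rng_seed=0, init_params=init
        )
        assert params.equal(init)
        assert history == []

    def test_fedopt_plain_unit_lr_reproduces_fedavg_trajectory(
        self, fl_setup, tiny_model_cfg
    ):
        train_by_center, val = fl_setup
        base = dict(local_epochs=1, rounds=2, client_lr=1e-3)
        favg = FLSchedule("fedavg", **base)
        fopt = FLSchedule("fedopt", **base, server_lr=1.0, fedopt_plain=True)
        a, _, _ = run_fl(train_by_center, val, favg, tiny_model_cfg, rng_seed=9)
        b, _, _ = run_fl(train_by_center, val, fopt, tiny_model_cfg, rng_seed=9)
        assert a.equal(b)

    def test_fedprox_mu_zero_reproduces_fedavg_trajectory(
        self, fl_setup, tiny_model_cfg
    ):
        train_by_center, val = fl_setup
        base = dict(local_epochs=1, rounds=2, client_lr=1e-3)
        favg = FLSchedule("fedavg", **base)
        fprox = FLSchedule("fedprox", **base, mu=0.0)
        a, _, _ = run_fl(train_by_center, val, favg, tiny_model_cfg, rng_seed=9)
        b, _, _ = run_fl(train_by_center, val, fprox, tiny_model_cfg, rng_seed=9)
        assert a.equal(b)

    def test_fedprox_mu_pulls_towards_global(self, fl_setup, tiny_model_cfg):
        """A large proximal coefficient keeps clients closer to the broadcast."""
        train_by_center, val = fl_setup
        net = HourglassNet(tiny_model_cfg)
        init = net.init_params(2)

        def client_drift(mu):
            sch = FLSchedule("fedprox", local_epochs=1, rounds=1, client_lr=1e-3, mu=mu)
            params, _, _ = run_fl(
                train_by_center, [], sch, tiny_model_cfg, rng_seed=3, init_params=init
            )
            return (params - init).sq_norm()

        assert client_drift(100.0) < client_drift(0.0)

    def test_privacy_contract_no_samples_cross_server_boundary(
        self, fl_setup, tiny_model_cfg
    ):
        train_by_center, _ = fl_setup
        clients = [
            Client(cid, s, seed=i) for i, (cid, s) in enumerate(train_by_center.items())
        ]
        net = HourglassNet(tiny_model_cfg)
        state = ServerState(global_params=net.init_params(0))
        sch = FLSchedule("fedavg", local_epochs=1, rounds=1, client_lr=1e-3)
        tcfg = TrainConfig(epochs=1, lr=1e-3, batch_size=8, augment=False)
        _, updates = run_round(state, clients, sch, tiny_model_cfg, tcfg)
        for u in updates:
            assert isinstance(u, ClientUpdate)
            assert set(vars(u)) == {"params", "n_samples", "client_id", "round_metrics"}
            assert isinstance(u.params, ParamVector)
            assert isinstance(u.n_samples, int)
            for v in u.round_metrics.values():
                assert np.isscalar(v)
            # nothing reachable from the update references a SpineSample
            for arr in u.params.arrays.values():
                assert isinstance(arr, np.ndarray)
            assert not any(
                isinstance(v, SpineSample) for v in vars(u).values()
            )


class TestSchedules:
    @pytest.mark.parametrize(
        "strategy,total",
        [("fedavg", 300), ("fedopt", 300), ("fedprox", 1000)],
    )
    def test_default_schedule_totals(self, strategy, total):
        assert FLSchedule.default(strategy).total_local_epochs == total

    def test_fedavg_client_lr_decays_after_15_rounds(self):
        sch = FLSchedule.default("fedavg")
        from fedspine.training import lr_schedule

        assert lr_schedule(14, sch.client_lr, sch.lr_decay_factor, sch.lr_decay_after) == pytest.approx(1e-4)
        assert lr_schedule(15, sch.client_lr, sch.lr_decay_factor, sch.lr_decay_after) == pytest.approx(1e-5)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            FLSchedule("fedsgd", 1, 1, 1e-3)
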