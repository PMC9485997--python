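"""Physics-informed neural fitters: architecture, loss, schedule, inference."""

import numpy as np
import pytest

from ivim3fit import (
    SimConfig,
    TriParams,
    simulate_batch,
    tri_signal,
)
from ivim3fit.models import ValidationError
from ivim3fit.nn import (
    NetworkSpec,
    TrainConfig,
    build_network,
    load_fitter,
    physics_loss,
    predict_maps,
    save_fitter,
    train,
    train_with_restarts,
)


@pytest.fixture(scope="module")
def small_batch():
    return simulate_batch(SimConfig(n_curves=2000, seed=31))


class TestBuildNetwork:
    def test_tri_semi_parallel_has_three_pair_subnets(self):
        net = build_network(NetworkSpec("tri"), n_b=18)
        assert len(net.subnets) == 3
        for subnet, group in zip(net.subnets, net.spec.groups):
            assert len(group) == 2
            assert subnet.layers[-1].W.shape[1] == 2

    def test_bi_has_four_subnets_with_two_hidden_layers(self):
        from ivim3fit._mlp import Linear

        net = build_network(NetworkSpec("bi"), n_b=18)
        assert len(net.subnets) == 4
        for subnet in net.subnets:
            linears = [l for l in subnet.layers if isinstance(l, Linear)]
            assert len(linears) == 3  # 2 hidden + 1 output

    def test_untrained_outputs_within_bounds(self, rng):
        net = build_network(NetworkSpec("tri"), n_b=18, seed=0)
        x = rng.normal(1.0, 0.5, size=(64, 18))
        out = net.forward(x, train=False)
        bounds = net.spec.output_bounds.bounds
        for name, values in out.items():
            lo, hi = bounds[name]
            assert values.min() > lo and values.max() < hi

    def test_too_few_bvalues_rejected(self):
        with pytest.raises(ValidationError):
            build_network(NetworkSpec("tri"), n_b=4)


class TestPhysicsLoss:
    def test_exact_parameters_give_zero_loss(self, bscheme, interior_tri_params):
        prime = interior_tri_params.to_prime()
        signals = tri_signal(interior_tri_params, bscheme)[None, :]
        assert physics_loss(prime, signals, bscheme, "tri") == pytest.approx(0.0, abs=1e-15)

    def test_known_residual_gives_closed_form_rmse(self, bscheme, interior_tri_params):
        prime = interior_tri_params.to_prime()
        signals = tri_signal(interior_tri_params, bscheme)[None, :]
        # constant offset c -> RMSE |c|
        assert physics_loss(prime, signals + 0.04, bscheme, "tri") == pytest.approx(0.04)

    def test_hand_computed_two_voxel_example(self, bscheme, interior_tri_params):
        n_b = len(bscheme)
        prime = interior_tri_params.to_prime()
        params = {
            k: np.repeat(np.atleast_1d(getattr(prime, k)), 2)
            for k in ("f0p", "f1p", "f2p", "D", "D1star", "D2star")
        }
        pred = np.tile(tri_signal(interior_tri_params, bscheme), (2, 1))
        delta = np.arange(2 * n_b).reshape(2, n_b) * 1e-3
        expected = float(np.sqrt((delta**2).sum() / delta.size))
        assert physics_loss(params, pred + delta, bscheme, "tri") == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_row_order(self, small_batch):
        net = build_network(NetworkSpec("tri"), 18, seed=1)
        x = small_batch.signals[:50]
        p = net.forward(x, train=False)
        loss = physics_loss(p, x, small_batch.bvalues, "tri")
        perm = np.random.default_rng(0).permutation(50)
        p_perm = {k: v[perm] for k, v in p.items()}
        assert physics_loss(p_perm, x[perm], small_batch.bvalues, "tri") == pytest.approx(loss)

    def test_shape_mismatch_rejected(self, small_batch):
        net = build_network(NetworkSpec("tri"), 18, seed=1)
        p = net.forward(small_batch.signals[:10], train=False)
        with pytest.raises(ValidationError):
            physics_loss(p, small_batch.signals[:9], small_batch.bvalues, "tri")


class TestTraining:
    def test_overfits_one_repeated_noiseless_curve(self, bscheme, interior_tri_params):
        # batch statistics are degenerate on identical rows, so the sanity
        # check runs without batch norm and dropout
        curve = tri_signal(interior_tri_params, bscheme)
        signals = np.tile(curve, (64, 1))
        spec = NetworkSpec("tri", dropout=0.0, batch_norm=False)
        net = build_network(spec, 18, seed=0)
        cfg = TrainConfig(initial_lr=1e-3, patience=50, max_epochs=1200, batch_size=32, seed=0)
        tf = train(net, signals, bscheme, cfg)
        assert tf.final_val_loss < 1e-3

    def test_fixed_seed_gives_identical_training_log(self, small_batch):
        logs = []
        for _ in range(2):
            net = build_network(NetworkSpec("tri"), 18, seed=5)
            cfg = TrainConfig(seed=5, max_epochs=4)
            tf = train(net, small_batch.signals, small_batch.bvalues, cfg)
            logs.append(tf.training_log)
        assert logs[0] == logs[1]

    def test_constructed_plateau_schedule_contract(self, small_batch):
        # zero learning rate + no batch-norm/dropout freezes the network:
        # the validation loss plateaus from epoch 2 onwards, so the
        # scheduler must reduce the rate by exactly x5 after `patience`
        # non-improving epochs and stop when the fresh rate brings no
        # improvement within `patience` more
        net = build_network(NetworkSpec("tri", dropout=0.0, batch_norm=False), 18, seed=6)
        cfg = TrainConfig(initial_lr=0.0, patience=10, max_epochs=100, seed=6)
        tf = train(net, small_batch.signals[:500], small_batch.bvalues, cfg)
        log = tf.training_log
        reductions = [e for e in log if e["lr_reduced"]]
        assert len(reductions) == 1
        assert reductions[0]["epoch"] == 1 + cfg.patience
        assert len(log) == 1 + 2 * cfg.patience  # halt: fresh lr never improved
        assert log[-1]["lr"] == pytest.approx(cfg.initial_lr / cfg.lr_decay_factor)

    def test_lr_reductions_divide_by_factor_after_patience(self, small_batch):
        net = build_network(NetworkSpec("tri"), 18, seed=7)
        cfg = TrainConfig(patience=2, max_epochs=40, seed=7)
        tf = train(net, small_batch.signals, small_batch.bvalues, cfg)
        log = tf.training_log
        assert any(e["lr_reduced"] for e in log)
        lr_prev = log[0]["lr"]
        counter = 0 if log[0]["improved"] else 1
        for entry in log[1:]:
            if entry["lr_reduced"]:
                # reduction fires after exactly `patience` non-improving
                # epochs (this epoch included) and divides the rate by 5
                assert counter + 1 == cfg.patience
                assert entry["lr"] == pytest.approx(lr_prev / 5.0)
                counter = 0
            elif entry["improved"]:
                counter = 0
            else:
                counter += 1
            lr_prev = entry["lr"]
        best_series = [e["best_val"] for e in log]
        assert all(b <= a + 1e-15 for a, b in zip(best_series, best_series[1:]))

    def test_bi_training_runs_and_stops_on_plateau(self, small_batch):
        net = build_network(NetworkSpec("bi"), 18, seed=8)
        cfg = TrainConfig(seed=8, patience=3, max_epochs=60)
        tf = train(net, small_batch.signals, small_batch.bvalues, cfg)
        assert tf.config.use_scheduler is False
        assert tf.config.initial_lr == pytest.approx(3e-5)
        assert len(tf.training_log) <= 60

    def test_training_never_reads_ground_truth(self, bscheme):
        # two simulations share signals but carry different truth objects;
        # training output depends on the signals alone
        batch = simulate_batch(SimConfig(n_curves=800, seed=41))
        signals_only = batch.signals.copy()
        del batch  # drop every reference to the ground truth
        logs = []
        for _ in range(2):
            net = build_network(NetworkSpec("tri"), 18, seed=9)
            tf = train(net, signals_only, bscheme, TrainConfig(seed=9, max_epochs=3))
            logs.append(tf.training_log)
        assert logs[0] == logs[1]


class TestRestartsAndInference:
    def test_single_restart_equals_plain_train(self, small_batch):
        cfg = TrainConfig(seed=12, max_epochs=3, n_restarts=1)
        net = build_network(NetworkSpec("tri"), 18, seed=12)
        direct = train(net, small_batch.signals, small_batch.bvalues, cfg)
        restarted = train_with_restarts(
            NetworkSpec("tri"), small_batch.signals, small_batch.bvalues, cfg
        )
        assert restarted.final_val_loss == pytest.approx(direct.final_val_loss)

    def test_returns_minimum_of_logged_restart_losses(self, small_batch):
        cfg = TrainConfig(seed=13, max_epochs=3, n_restarts=3)
        tf = train_with_restarts(
            NetworkSpec("tri"), small_batch.signals, small_batch.bvalues, cfg
        )
        assert len(tf.restart_losses) == 3
        assert tf.final_val_loss == min(tf.restart_losses)

    def test_identical_voxels_get_identical_predictions(self, small_batch):
        cfg = TrainConfig(seed=14, max_epochs=2)
        net = build_network(NetworkSpec("tri"), 18, seed=14)
        tf = train(net, small_batch.signals, small_batch.bvalues, cfg)
        x = np.tile(small_batch.signals[0], (2, 1))
        report = predict_maps(tf, x, small_batch.bvalues)
        maps = report.maps()
        for name in ("D", "D1star", "D2star", "f1", "f2"):
            values = np.asarray(maps[name])
            assert values[0] == values[1]

    def test_predictions_within_bounds_and_f12_emitted(self, small_batch):
        cfg = TrainConfig(seed=15, max_epochs=2)
        net = build_network(NetworkSpec("tri"), 18, seed=15)
        tf = train(net, small_batch.signals, small_batch.bvalues, cfg)
        report = predict_maps(tf, small_batch.signals, small_batch.bvalues)
        maps = report.maps()
        assert "f1plus2" in maps
        d1 = np.asarray(maps["D1star"])
        assert d1.min() > 8e-3 and d1.max() < 80e-3
        prime_out = tf.network.forward(small_batch.signals, train=False)
        assert tf.spec.output_bounds.contains(prime_out)

    def test_mismatched_bvalue_scheme_rejected(self, small_batch):
        cfg = TrainConfig(seed=16, max_epochs=2)
        net = build_network(NetworkSpec("tri"), 18, seed=16)
        tf = train(net, small_batch.signals, small_batch.bvalues, cfg)
        with pytest.raises(ValidationError):
            predict_maps(tf, small_batch.signals, np.linspace(0, 800, 18))

    def test_save_load_round_trip(self, small_batch, tmp_path):
        cfg = TrainConfig(seed=17, max_epochs=2)
        net = build_network(NetworkSpec("tri"), 18, seed=17)
        tf = train(net, small_batch.signals, small_batch.bvalues, cfg)
        path = tmp_path / "fitter.npz"
        save_fitter(tf, path)
        tf2 = load_fitter(path)
        a = predict_maps(tf, small_batch.signals[:20], small_batch.bvalues)
        b = predict_maps(tf2, small_batch.signals[:20], small_batch.bvalues)
        np.testing.assert_array_equal(np.asarray(a.maps()["D"]), np.asarray(b.maps()["D"]))
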