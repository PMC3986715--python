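"""Perceptron forward pass, Levenberg-Marquardt training, splits, R², sweep."""

import math

import numpy as np
import pytest

from dissopt import (
    CANONICAL_TIMES_H,
    Formulation,
    FormulationDataset,
    DissolutionProfile,
    MLPSurrogate,
    ScalerParams,
    SplitSpec,
    TrainingLimits,
    evaluate_r2,
    forward,
    forward_batch,
    load_model,
    node_sweep,
    retrain_full,
    save_model,
    split_dataset,
    train,
)
from dissopt.scaling import apply_scaler, invert_scaler


def _random_net(rng, n_hidden, n_in=4, n_out=6):
    return MLPSurrogate(
        input_weights=rng.normal(size=(n_hidden, n_in)),
        input_biases=rng.normal(size=n_hidden),
        output_weights=rng.normal(size=(n_out, n_hidden)),
        output_biases=rng.normal(size=n_out),
        input_scaler=ScalerParams((0, 0, 0, 4), (120, 100, 20, 20)),
        target_scaler=ScalerParams((20,) * n_out, (100,) * n_out),
        times_h=CANONICAL_TIMES_H,
    )


def _loop_forward(net, x):
    """Independent brute-force evaluation: explicit loops over nodes."""
    xs = [
        2 * (v - lo) / (hi - lo) - 1
        for v, lo, hi in zip(x, net.input_scaler.minimum, net.input_scaler.maximum)
    ]
    hidden = []
    for h in range(net.n_hidden):
        s = net.input_biases[h]
        for i, xi in enumerate(xs):
            s += net.input_weights[h, i] * xi
        hidden.append(1.0 / (1.0 + math.exp(-s)))
    out = []
    for o in range(len(net.times_h)):
        s = net.output_biases[o]
        for h, ah in enumerate(hidden):
            s += net.output_weights[o, h] * ah
        lo = net.target_scaler.minimum[o]
        hi = net.target_scaler.maximum[o]
        out.append((s + 1) * (hi - lo) / 2 + lo)
    return out


class TestForward:
    def test_matches_explicit_loop_evaluation(self, rng):
        for _ in range(100):
            net = _random_net(rng, n_hidden=int(rng.integers(1, 8)))
            x = rng.uniform([0, 0, 0, 4], [120, 100, 20, 20])
            fast = forward_batch(net, x[None, :])[0]
            slow = _loop_forward(net, x)
            np.testing.assert_allclose(fast, slow, rtol=1e-12, atol=1e-12)

    def test_zero_net_predicts_target_range_midpoints(self):
        net = MLPSurrogate(
            np.zeros((3, 4)), np.zeros(3), np.zeros((6, 3)), np.zeros(6),
            ScalerParams((0, 0, 0, 4), (120, 100, 20, 20)),
            ScalerParams((20, 30, 40, 50, 60, 80), (40, 50, 60, 70, 90, 100)),
            CANONICAL_TIMES_H,
        )
        prof = forward(net, Formulation(60, 50, 10, 12))
        assert prof.release_pct == (30, 40, 50, 60, 75, 90)

    def test_single_node_hand_arithmetic(self):
        # one hidden node, hand-set weights; evaluated by hand:
        # xs = (0, 0, 0, 0) at the domain center -> z = 0.3,
        # a = 1/(1+e^-0.3), y_scaled = 2a - 0.5, y = (y_scaled+1)*50
        net = MLPSurrogate(
            np.array([[0.1, 0.2, 0.3, 0.4]]), np.array([0.3]),
            np.full((6, 1), 2.0), np.full(6, -0.5),
            ScalerParams((0, 0, 0, 4), (120, 100, 20, 20)),
            ScalerParams((0,) * 6, (100,) * 6),
            CANONICAL_TIMES_H,
        )
        a = 1 / (1 + math.exp(-0.3))
        expected = (2 * a - 0.5 + 1) * 50
        prof = forward(net, Formulation(60, 50, 10, 12))
        np.testing.assert_allclose(prof.release_pct, [expected] * 6, rtol=1e-12)

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError):
            MLPSurrogate(
                np.full((1, 4), np.nan), np.zeros(1), np.zeros((6, 1)),
                np.zeros(6),
                ScalerParams((0, 0, 0, 4), (120, 100, 20, 20)),
                ScalerParams((0,) * 6, (100,) * 6),
                CANONICAL_TIMES_H,
            )


class TestSplit:
    def test_30_records_give_20_7_3(self, study):
        tr, va, te = split_dataset(study, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (20, 7, 3)
        assert sorted(tr + va + te) == list(range(30))

    def test_deterministic_given_seed(self, study):
        assert split_dataset(study, SplitSpec(seed=5)) == split_dataset(
            study, SplitSpec(seed=5)
        )
        assert split_dataset(study, SplitSpec(seed=5)) != split_dataset(
            study, SplitSpec(seed=6)
        )

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0)

    def test_empty_partition_rejected(self, study):
        with pytest.raises(ValueError, match="empty partition"):
            split_dataset(study, SplitSpec(train_fraction=0.95, seed=0))


def _realizable_dataset(n_hidden=1, n=30, seed=3):
    """Noiseless targets generated by a known small network."""
    rng = np.random.default_rng(seed)
    net = _random_net(rng, n_hidden)
    X = rng.uniform([0, 0, 0, 4], [120, 100, 20, 20], size=(n, 4))
    Y = forward_batch(net, X)
    records = []
    for i in range(n):
        records.append(
            (
                f"R{i:03d}",
                Formulation(*X[i], check=False),
                DissolutionProfile(CANONICAL_TIMES_H, Y[i]),
            )
        )
    return FormulationDataset(records)


class TestTraining:
    def test_realizable_function_recovered(self):
        ds = _realizable_dataset(n_hidden=1)
        net, hist = train(ds, 1, seed=0)
        assert hist.train_mse[-1] < 1e-6

    def test_accepted_training_mse_non_increasing(self, study):
        _, hist = train(study, 4, seed=1)
        mse = np.array(hist.train_mse)
        assert np.all(np.diff(mse) <= 0)

    def test_deterministic_given_seed(self, study):
        n1, h1 = train(study, 3, seed=9)
        n2, h2 = train(study, 3, seed=9)
        np.testing.assert_array_equal(n1.input_weights, n2.input_weights)
        assert h1.train_mse == h2.train_mse

    def test_best_validation_checkpoint_restored(self, study):
        net, hist = train(study, 8, seed=2)
        assert hist.best_validation_mse == min(hist.validation_mse)
        assert hist.stop_reason in {
            "max_epochs", "validation_failures", "gradient_converged"
        }
        # restored weights reproduce the best validation error
        spec = SplitSpec(seed=2)
        _, idx_val, _ = split_dataset(study, spec)
        from dissopt.scaling import fit_scaler

        tgt = fit_scaler(study.targets())
        ins = fit_scaler(study.inputs())
        Xs = apply_scaler(ins, study.inputs()[list(idx_val)])
        Ts = apply_scaler(tgt, study.targets()[list(idx_val)])
        from dissopt.surrogate import _forward_scaled

        pred = _forward_scaled(
            net.input_weights, net.input_biases,
            net.output_weights, net.output_biases, Xs,
        )
        assert float(np.mean((pred - Ts) ** 2)) == pytest.approx(
            hist.best_validation_mse, rel=1e-12
        )

    def test_matches_linear_least_squares_in_linear_regime(self, rng):
        # targets exactly linear in the inputs: the normal-equations
        # solution is an independent oracle the trainer must approach
        X = rng.uniform([0, 0, 0, 4], [120, 100, 20, 20], size=(25, 4))
        from dissopt.scaling import fit_scaler

        ins = fit_scaler(X)
        Xs = apply_scaler(ins, X)
        # rank-1 coefficient matrix: within a 2-node network's linear span
        B = np.outer(rng.uniform(-0.1, 0.1, 4), rng.uniform(-0.5, 0.5, 6))
        Ys_scaled = Xs @ B  # small amplitude keeps the sigmoid near-linear
        lo = np.full(6, 20.0)
        hi = np.full(6, 80.0)
        Y = invert_scaler(ScalerParams(tuple(lo), tuple(hi)), Ys_scaled)
        ds = FormulationDataset(
            (
                f"L{i:02d}",
                Formulation(*X[i], check=False),
                DissolutionProfile(CANONICAL_TIMES_H, Y[i]),
            )
            for i in range(25)
        )
        net = retrain_full(ds, 2, seed=0)
        pred = forward_batch(net, X)
        # scaled-unit MSE, same loss the trainer minimizes
        tgt = fit_scaler(Y)
        resid = apply_scaler(tgt, pred) - apply_scaler(tgt, Y)
        mlp_mse = float(np.mean(resid**2))
        A = np.hstack([Xs, np.ones((25, 1))])
        coef, *_ = np.linalg.lstsq(A, apply_scaler(tgt, Y), rcond=None)
        ls_mse = float(np.mean((A @ coef - apply_scaler(tgt, Y)) ** 2))
        assert mlp_mse <= ls_mse + 1e-6

    def test_matches_scipy_lm_oracle_on_small_problem(self):
        # independent optimizer route: scipy's Levenberg-Marquardt driver
        # on the identical residual function reaches a comparable loss
        scipy_opt = pytest.importorskip("scipy.optimize")
        from dissopt.surrogate import _init_params, _mse, _residuals

        ds = _realizable_dataset(n_hidden=2, n=20, seed=6)
        from dissopt.scaling import fit_scaler

        ins = fit_scaler(ds.inputs())
        tgt = fit_scaler(ds.targets())
        Xs = apply_scaler(ins, ds.inputs())
        Ts = apply_scaler(tgt, ds.targets())
        p0 = _init_params(2, 4, 6, np.random.default_rng(0))
        sol = scipy_opt.least_squares(
            lambda p: _residuals(p, 2, Xs, Ts), p0, method="lm", max_nfev=20000
        )
        scipy_mse = _mse(sol.x, 2, Xs, Ts)
        net = retrain_full(ds, 2, seed=0)
        from dissopt.surrogate import _pack

        ours = _mse(
            _pack(net.input_weights, net.input_biases,
                  net.output_weights, net.output_biases),
            2, Xs, Ts,
        )
        assert ours <= scipy_mse + 1e-6

    def test_invalid_n_hidden(self, study):
        with pytest.raises(ValueError):
            train(study, 0)


class TestRetrainFull:
    def test_realizable_recovery_and_determinism(self):
        ds = _realizable_dataset(n_hidden=1)
        a = retrain_full(ds, 1, seed=4)
        b = retrain_full(ds, 1, seed=4)
        np.testing.assert_array_equal(a.output_weights, b.output_weights)
        X = ds.inputs()
        np.testing.assert_allclose(
            forward_batch(a, X), ds.targets(), atol=0.2
        )


class TestEvaluateR2:
    def test_perfect_predictions_score_one(self):
        ds = _realizable_dataset(n_hidden=2, n=12, seed=8)
        rng = np.random.default_rng(8)
        net = _random_net(rng, 2)  # same stream -> the generating network
        r2 = evaluate_r2(net, ds)
        np.testing.assert_allclose(r2, np.ones(6), atol=1e-9)

    def test_constant_predictions_reported_as_zero_with_warning(self, study):
        net = MLPSurrogate(
            np.zeros((2, 4)), np.zeros(2), np.zeros((6, 2)), np.zeros(6),
            ScalerParams((0, 0, 0, 4), (120, 100, 20, 20)),
            ScalerParams((0,) * 6, (100,) * 6),
            CANONICAL_TIMES_H,
        )
        with pytest.warns(UserWarning, match="constant predictions"):
            r2 = evaluate_r2(net, study)
        assert np.all(r2 == 0.0)

    def test_zero_observed_variance_reported_missing(self, rng):
        net = _random_net(rng, 2)
        f = Formulation(60, 50, 10, 12)
        p = DissolutionProfile(CANONICAL_TIMES_H, [30, 40, 50, 60, 70, 80])
        ds = FormulationDataset([("A", f, p), ("B", f, p)])
        r2 = evaluate_r2(net, ds)
        assert np.all(np.isnan(r2))

    def test_empty_subset_rejected(self, rng):
        net = _random_net(rng, 2)
        with pytest.raises(ValueError):
            evaluate_r2(net, FormulationDataset([]))


class TestNodeSweep:
    def test_deterministic_given_seed(self, study):
        limits = TrainingLimits(max_epochs=40)
        t1, s1 = node_sweep(study, [2, 3], repeats=2, seed=5, limits=limits)
        t2, s2 = node_sweep(study, [2, 3], repeats=2, seed=5, limits=limits)
        assert s1 == s2
        assert t1.equals(t2)

    def test_capacity_at_realizable_point(self):
        ds = _realizable_dataset(n_hidden=2, n=30, seed=10)
        table, selected = node_sweep(
            ds, [1, 2, 8], repeats=3, seed=0, limits=TrainingLimits(max_epochs=150)
        )
        by_nodes = table.set_index("n_hidden")["mean_r2"]
        assert by_nodes[selected] >= by_nodes[1]

    def test_candidate_bounds(self, study):
        with pytest.raises(ValueError):
            node_sweep(study, [0, 3], repeats=1)
        with pytest.raises(ValueError):
            node_sweep(study, [], repeats=1)


class TestSerialization:
    def test_round_trip_is_exact(self, study, tmp_path):
        net, _ = train(study, 3, limits=TrainingLimits(max_epochs=30), seed=0)
        path = tmp_path / "model.json"
        save_model(net, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.input_weights, net.input_weights)
        np.testing.assert_array_equal(back.output_biases, net.output_biases)
        assert back.input_scaler == net.input_scaler
        assert back.times_h == net.times_h

    def test_rejects_foreign_files(self, tmp_path):
        p = tmp_path / "x.json"
        p.write_text('{"format": "other"}')
        with pytest.raises(ValueError):
            load_model(p)
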