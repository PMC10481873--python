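"""Classifier: initialization, forward pass, loss, training, persistence."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from herbscreen.ndcnn import (
    NDCNNConfig,
    NDCNNModel,
    _backward_full,
    _forward_full,
    compile_binary_scorer,
    cross_entropy,
    evaluate,
    forward,
    init_model,
    load_checkpoint,
    load_model,
    make_scorer,
    predict_effective_prob,
    save_model,
    train,
)
from herbscreen.prescriptions import EncodedCohort
from herbscreen.synthetic_data import SyntheticSpec, generate_cohort

SMALL = NDCNNConfig(
    input_dim=8,
    branch_kernel_sizes=(1, 3),
    branch_filters=2,
    second_kernel_size=3,
    second_filters=2,
    fc_sizes=(4,),
    pooling_mode="local_max",
    pool_size=3,
    dtype="float64",
    seed=11,
)


def naive_forward(model: NDCNNModel, x: np.ndarray) -> np.ndarray:
    """Straight-line reference of the forward arithmetic: explicit loops only."""
    cfg, p = model.config, model.params
    d = cfg.input_dim
    branch_out = []
    for k in cfg.branch_kernel_sizes:
        W, b = p[f"branch{k}_W"], p[f"branch{k}_b"]
        pad = (k - 1) // 2
        out = np.zeros((d, cfg.branch_filters))
        for pos in range(d):
            for f in range(cfg.branch_filters):
                s = b[f]
                for j in range(k):
                    src = pos + j - pad
                    if 0 <= src < d:
                        s += W[f, j] * x[src]
                out[pos, f] = max(s, 0.0)
        branch_out.append(out)
    A = np.concatenate(branch_out, axis=1)

    k2, pad2 = cfg.second_kernel_size, (cfg.second_kernel_size - 1) // 2
    W2, b2 = p["conv2_W"], p["conv2_b"]
    A2 = np.zeros((d, cfg.second_filters))
    for pos in range(d):
        for f in range(cfg.second_filters):
            s = b2[f]
            for j in range(k2):
                src = pos + j - pad2
                if 0 <= src < d:
                    for c in range(A.shape[1]):
                        s += W2[f, j, c] * A[src, c]
            A2[pos, f] = max(s, 0.0)

    if cfg.pooling_mode == "global_max":
        h = A2.max(axis=0)
    elif cfg.pooling_mode == "local_max":
        cells = []
        for start in range(0, d, cfg.pool_size):
            cells.append(A2[start : start + cfg.pool_size].max(axis=0))
        h = np.concatenate(cells)
    else:
        h = A2.reshape(-1)

    for i in range(len(cfg.fc_sizes)):
        h = np.maximum(p[f"fc{i}_W"] @ h + p[f"fc{i}_b"], 0.0)
    logits = p["out_W"] @ h + p["out_b"]
    e = np.exp(logits - logits.max())
    return e / e.sum()


def _zero_model(config: NDCNNConfig) -> NDCNNModel:
    model = init_model(config)
    for k in model.params:
        model.params[k] = np.zeros_like(model.params[k])
    return model


class TestInit:
    def test_same_seed_bitwise_identical(self):
        a, b = init_model(SMALL, seed=3), init_model(SMALL, seed=3)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_default_architecture_shapes(self):
        model = init_model(NDCNNConfig(seed=0))
        for k in (1, 3, 5):
            assert model.params[f"branch{k}_W"].shape == (128, k)
        assert model.params["conv2_W"].shape == (128, 3, 384)
        assert model.params["out_W"].shape[0] == 2

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            NDCNNConfig(branch_kernel_sizes=(2,))
        with pytest.raises(ValueError):
            NDCNNConfig(output_size=3)


class TestForward:
    def test_zero_parameters_give_half_half(self, rng):
        model = _zero_model(SMALL)
        x = (rng.random((5, 8)) < 0.5).astype(np.uint8)
        probs = forward(model, x).probabilities
        assert np.allclose(probs, 0.5)
        assert predict_effective_prob(model, x[0]) == pytest.approx(0.5)

    @given(st.integers(0, 2**8 - 1), st.integers(0, 10_000))
    def test_probabilities_sum_to_one(self, bits, seed):
        model = init_model(SMALL, seed=seed % 50)
        x = np.array([(bits >> i) & 1 for i in range(8)], dtype=np.uint8)
        probs = forward(model, x[None, :]).probabilities
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert (probs >= 0).all()

    @pytest.mark.parametrize("pooling", ["local_max", "global_max", "flatten"])
    def test_matches_straight_line_oracle(self, pooling, rng):
        import dataclasses

        cfg = dataclasses.replace(SMALL, pooling_mode=pooling)
        model = init_model(cfg, seed=21)
        for k, v in model.params.items():
            if k.endswith("_b"):
                model.params[k] = rng.normal(0, 0.3, v.shape)
        for _ in range(5):
            x = (rng.random(8) < 0.5).astype(np.float64)
            expected = naive_forward(model, x)
            got = forward(model, x[None, :]).probabilities[0]
            assert np.allclose(got, expected, atol=1e-12)

    def test_dimension_mismatch_error(self):
        model = init_model(SMALL)
        with pytest.raises(ValueError):
            forward(model, np.zeros((2, 9)))
        with pytest.raises(ValueError):
            predict_effective_prob(model, np.zeros(9))

    def test_non_binary_input_warns(self):
        model = init_model(SMALL)
        with pytest.warns(UserWarning, match="binary"):
            forward(model, np.full((1, 8), 0.5))


class TestCrossEntropy:
    def test_exact_prediction_is_zero(self):
        t = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy(t, t) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_is_ln2(self):
        pred = np.array([[0.5, 0.5]])
        assert cross_entropy(pred, np.array([[1.0, 0.0]])) == pytest.approx(np.log(2))

    def test_three_row_mean_matches_hand_arithmetic(self):
        pred = np.array([[0.9, 0.1], [0.2, 0.8], [0.6, 0.4]])
        targets = np.array([[1, 0], [0, 1], [0, 1]], dtype=float)
        expected = -(np.log(0.9) + np.log(0.8) + np.log(0.4)) / 3
        assert cross_entropy(pred, targets) == pytest.approx(expected)

    def test_shape_mismatch_error(self):
        with pytest.raises(ValueError):
            cross_entropy(np.ones((2, 2)) / 2, np.ones((3, 2)))

    def test_clipping_keeps_loss_finite(self):
        pred = np.array([[1.0, 0.0]])
        assert np.isfinite(cross_entropy(pred, np.array([[0.0, 1.0]])))


class TestGradients:
    def test_finite_difference_agreement(self, rng):
        cfg = NDCNNConfig(
            input_dim=16,
            branch_filters=4,
            second_filters=4,
            fc_sizes=(8, 4),
            dtype="float64",
            seed=3,
        )
        model = init_model(cfg)
        # random biases keep pre-activations off the ReLU kink
        for k, v in model.params.items():
            if k.endswith("_b"):
                model.params[k] = rng.normal(0, 0.1, v.shape)
        X = (rng.random((8, 16)) < 0.4).astype(np.float64)
        T = np.eye(2)[rng.integers(0, 2, 8)]
        grads = _backward_full(model, _forward_full(model, X), T)

        def loss():
            return cross_entropy(_forward_full(model, X)["probs"], T)

        h = 1e-6
        for name, g in grads.items():
            p = model.params[name]
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = p[ix]
                p[ix] = orig + h
                lp = loss()
                p[ix] = orig - h
                lm = loss()
                p[ix] = orig
                num = (lp - lm) / (2 * h)
                rel = abs(num - g[ix]) / max(abs(num), abs(g[ix]), 1e-8)
                assert rel <= 1e-4, f"{name}{ix}: {g[ix]} vs {num}"


def _separable_cohort(seed=0):
    spec = SyntheticSpec(
        n_records=120,
        vocab_size=20,
        core_herbs=(7,),
        core_effect=60.0,
        intercept=-30.0,
        label_noise=0.0,
        formula_size_range=(3, 8),
        block_size=2,
        seed=seed,
    )
    return generate_cohort(spec).cohort


TRAIN_CFG = NDCNNConfig(
    input_dim=20,
    branch_filters=8,
    second_filters=8,
    fc_sizes=(32,),
    epochs=25,
    batch_size=8,
    seed=5,
)


class TestTraining:
    def test_separable_signal_reaches_full_train_accuracy(self):
        from herbscreen.prescriptions import SplitSpec, split

        cohort = _separable_cohort()
        tr, te = split(cohort, SplitSpec(seed=1))
        _, hist = train(init_model(TRAIN_CFG), tr, te)
        assert len(hist) == 25
        assert hist.train_accuracy.max() == pytest.approx(1.0)
        # loss trend non-increasing within tolerance
        diffs = np.diff(hist.train_loss)
        assert (diffs <= 0.05).all()

    def test_identical_seeds_identical_history(self):
        from herbscreen.prescriptions import SplitSpec, split

        cohort = _separable_cohort()
        tr, te = split(cohort, SplitSpec(seed=1))
        _, h1 = train(init_model(TRAIN_CFG), tr, te)
        _, h2 = train(init_model(TRAIN_CFG), tr, te)
        assert np.array_equal(h1.train_loss, h2.train_loss)
        assert np.array_equal(h1.test_accuracy, h2.test_accuracy)

    def test_empty_training_set_error(self):
        cohort = _separable_cohort()
        empty = EncodedCohort(
            np.zeros((0, 20), dtype=np.uint8), np.zeros(0, dtype=np.uint8), ()
        )
        with pytest.raises(ValueError):
            train(init_model(TRAIN_CFG), empty, cohort)

    def test_history_csv_round_trip(self, tmp_path):
        import pandas as pd

        from herbscreen.prescriptions import SplitSpec, split

        cohort = _separable_cohort()
        tr, te = split(cohort, SplitSpec(seed=1))
        import dataclasses

        cfg = dataclasses.replace(TRAIN_CFG, epochs=2)
        _, hist = train(init_model(cfg), tr, te)
        hist.to_csv(tmp_path / "history.csv")
        df = pd.read_csv(tmp_path / "history.csv")
        assert list(df.columns) == ["epoch", "train_loss", "test_loss", "train_acc", "test_acc"]
        assert len(df) == 2
        assert df["test_acc"].between(0, 1).all()


class TestEvaluate:
    def test_constant_model_accuracy_and_loss(self):
        model = _zero_model(SMALL)
        model.params["out_b"] = np.array([0.0, 1.0])
        labels = np.array([1, 1, 0, 1], dtype=np.uint8)
        cohort = EncodedCohort(
            np.eye(4, 8, dtype=np.uint8), labels, ("a", "b", "c", "d")
        )
        loss, acc = evaluate(model, cohort)
        assert acc == pytest.approx(0.75)
        p1 = np.exp(1) / (1 + np.exp(1))
        expected = -(3 * np.log(p1) + np.log(1 - p1)) / 4
        assert loss == pytest.approx(expected, rel=1e-6)

    def test_zero_model_predicts_class_zero_everywhere(self):
        model = _zero_model(SMALL)
        labels = np.array([0, 0, 0, 1, 1], dtype=np.uint8)
        cohort = EncodedCohort(
            np.eye(5, 8, dtype=np.uint8), labels, tuple("abcde")
        )
        _, acc = evaluate(model, cohort)
        assert acc == pytest.approx(3 / 5)  # tie-break toward "ineffective"


class TestCheckpoints:
    def test_round_trip_bitwise(self, tmp_path):
        model = init_model(SMALL, seed=9)
        path = tmp_path / "model.npz"
        save_model(model, path, vocab_names=[f"h{i}" for i in range(8)])
        loaded, vocab = load_checkpoint(path)
        assert loaded.config == model.config
        assert vocab == tuple(f"h{i}" for i in range(8))
        assert all(np.array_equal(loaded.params[k], model.params[k]) for k in model.params)

    def test_predictions_survive_round_trip(self, tmp_path, rng):
        model = init_model(SMALL, seed=9)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        x = (rng.random((4, 8)) < 0.5).astype(np.uint8)
        assert np.array_equal(
            forward(model, x).probabilities, forward(loaded, x).probabilities
        )

    def test_tampered_parameter_shape_rejected(self, tmp_path):
        model = init_model(SMALL, seed=9)
        path = tmp_path / "model.npz"
        save_model(model, path)
        with np.load(path, allow_pickle=False) as data:
            payload = {k: data[k] for k in data.files}
        payload["param:out_W"] = np.zeros((2, 99))
        np.savez(tmp_path / "bad.npz", **payload)
        with pytest.raises(ValueError, match="out_W"):
            load_model(tmp_path / "bad.npz")

    def test_non_checkpoint_rejected(self, tmp_path):
        np.savez(tmp_path / "junk.npz", foo=np.zeros(3))
        with pytest.raises(ValueError):
            load_model(tmp_path / "junk.npz")


class TestCompiledScorer:
    @pytest.mark.parametrize("pooling", ["local_max", "global_max", "flatten"])
    def test_matches_forward_on_binary_inputs(self, pooling, rng):
        import dataclasses

        cfg = dataclasses.replace(SMALL, pooling_mode=pooling, input_dim=30)
        model = init_model(cfg, seed=13)
        scorer = compile_binary_scorer(model)
        X = (rng.random((40, 30)) < 0.3).astype(np.uint8)
        X[0] = 0  # all-absent
        X[1] = 1  # all-present
        ref = forward(model, X).probabilities[:, 1]
        assert np.allclose(scorer(X), ref, atol=1e-9)
        assert scorer(X[2]) == pytest.approx(ref[2], abs=1e-9)

    def test_wide_kernels_fall_back_to_forward(self, rng):
        cfg = NDCNNConfig(
            input_dim=30,
            branch_kernel_sizes=(1, 11),
            branch_filters=2,
            second_filters=2,
            fc_sizes=(4,),
            dtype="float64",
            seed=2,
        )
        model = init_model(cfg)
        with pytest.raises(ValueError):
            compile_binary_scorer(model)
        scorer = make_scorer(model)
        x = (rng.random(30) < 0.5).astype(np.uint8)
        assert scorer(x) == pytest.approx(predict_effective_prob(model, x))
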