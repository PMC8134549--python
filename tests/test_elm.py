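import numpy as np
import pytest

from mielm import DataError, UsageError, hidden_matrix, predict, train_elm
from mielm.elm import ELMModel, _one_hot


def manual_model(W, b, beta=None, activation="sigmoid"):
    W = np.atleast_2d(np.asarray(W, dtype=float))
    n_hidden = W.shape[0]
    if beta is None:
        beta = np.zeros((n_hidden, 2))
    return ELMModel(
        input_weights=W,
        biases=np.asarray(b, dtype=float),
        output_weights=np.asarray(beta, dtype=float),
        activation=activation,
        seed=0,
        class_labels=np.array([1, 2]),
        class_names=["a", "b"],
    )


class TestHiddenMatrix:
    def test_zero_weights_give_half(self):
        model = manual_model(np.zeros((3, 2)), np.zeros(3))
        H = hidden_matrix(model, np.random.default_rng(0).standard_normal((5, 2)))
        np.testing.assert_allclose(H, 0.5)

    def test_single_unit(self):
        model = manual_model([[1.0]], [0.0])
        H = hidden_matrix(model, [[0.0]])
        np.testing.assert_allclose(H, [[0.5]])

    def test_dimension_mismatch(self):
        model = manual_model(np.zeros((3, 2)), np.zeros(3))
        with pytest.raises(UsageError):
            hidden_matrix(model, np.zeros((5, 4)))


class TestTrainElm:
    def test_square_invertible_interpolates(self, rng):
        X = rng.standard_normal((12, 3))
        labels = rng.integers(1, 3, size=12)
        model = train_elm(X, labels, n_hidden=12, seed=5)
        H = hidden_matrix(model, X)
        T = _one_hot(labels, model.class_labels)
        assert np.linalg.norm(H @ model.output_weights - T) < 1e-6
        pred, _ = predict(model, X)
        assert np.array_equal(pred, labels)

    def test_xor_problem(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        labels = np.array([1, 2, 2, 1])
        model = train_elm(X, labels, n_hidden=10, seed=3)
        pred, _ = predict(model, X)
        assert np.array_equal(pred, labels)
        # beta must match an explicit SVD pseudoinverse oracle
        H = hidden_matrix(model, X)
        U, s, Vt = np.linalg.svd(H, full_matrices=False)
        keep = s > 1e-12 * s.max()
        H_pinv = (Vt[keep].T / s[keep]) @ U[:, keep].T
        np.testing.assert_allclose(
            model.output_weights, H_pinv @ _one_hot(labels, model.class_labels), atol=1e-8
        )

    def test_determinism(self, rng):
        X = rng.standard_normal((20, 4))
        labels = rng.integers(1, 3, size=20)
        m1 = train_elm(X, labels, n_hidden=15, seed=42)
        m2 = train_elm(X, labels, n_hidden=15, seed=42)
        np.testing.assert_array_equal(m1.input_weights, m2.input_weights)
        np.testing.assert_array_equal(m1.output_weights, m2.output_weights)
        m3 = train_elm(X, labels, n_hidden=15, seed=43)
        assert not np.array_equal(m1.input_weights, m3.input_weights)

    def test_least_squares_global_optimum(self, rng):
        """The pseudoinverse solution attains the dense-lstsq residual for any seed."""
        for seed in range(5):
            X = rng.standard_normal((30, 6))
            labels = rng.integers(1, 4, size=30)
            model = train_elm(X, labels, n_hidden=10, seed=seed)
            H = hidden_matrix(model, X)
            T = _one_hot(labels, model.class_labels)
            beta_oracle, *_ = np.linalg.lstsq(H, T, rcond=None)
            assert np.linalg.norm(H @ model.output_weights - T) <= (
                np.linalg.norm(H @ beta_oracle - T) + 1e-8
            )

    def test_minimal_norm_on_underdetermined_systems(self, rng):
        """With N < N' the returned beta has minimal norm among equal-residual solutions."""
        for trial in range(20):
            X = rng.standard_normal((8, 3))
            labels = rng.integers(1, 3, size=8)
            model = train_elm(X, labels, n_hidden=20, seed=trial)
            H = hidden_matrix(model, X)
            beta = model.output_weights
            # perturbations confined to the null space keep the residual unchanged
            _, s, Vt = np.linalg.svd(H)
            null = Vt[s.size :]  # rows spanning the null space of H
            for _ in range(5):
                delta = (rng.standard_normal(null.shape[0]) @ null)[:, None]
                perturbed = beta + delta @ np.ones((1, beta.shape[1]))
                assert np.linalg.norm(beta) <= np.linalg.norm(perturbed) + 1e-8

    def test_monotone_capacity(self, rng):
        X = rng.standard_normal((60, 5))
        labels = rng.integers(1, 3, size=60)
        errors = []
        for n_hidden in [5, 10, 20, 40]:
            model = train_elm(X, labels, n_hidden=n_hidden, seed=7)
            H = hidden_matrix(model, X)
            T = _one_hot(labels, model.class_labels)
            errors.append(np.linalg.norm(H @ model.output_weights - T))
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(errors, errors[1:]))

    def test_validation_errors(self, rng):
        with pytest.raises(UsageError):
            train_elm(np.zeros((0, 2)), [], n_hidden=5, seed=0)
        with pytest.raises(DataError):
            train_elm(np.array([[np.nan, 1.0]]), [1], n_hidden=2, seed=0)
        with pytest.raises(UsageError):
            train_elm(rng.standard_normal((4, 2)), [1, 2, 1, 2], n_hidden=0, seed=0)
        with pytest.raises(UsageError):
            train_elm(rng.standard_normal((4, 2)), [1, 2, 1, 2], n_hidden=2, seed=0, activation="relu")

    def test_oversized_hidden_layer_warns(self, rng, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="mielm.elm"):
            train_elm(rng.standard_normal((4, 2)), [1, 2, 1, 2], n_hidden=50, seed=0)
        assert any("n_hidden" in rec.message for rec in caplog.records)

    def test_ridge_variant_smoke(self, rng):
        X = rng.standard_normal((20, 4))
        labels = rng.integers(1, 3, size=20)
        model = train_elm(X, labels, n_hidden=10, seed=1, ridge=1e-3)
        pred, _ = predict(model, X)
        assert pred.shape == (20,)


class TestPredict:
    def test_argmax_and_tie_rule(self):
        model = manual_model(np.zeros((2, 1)), np.zeros(2), beta=np.eye(2))
        # H is all 0.5 -> raw outputs (0.5, 0.5): tie resolves to class 1
        pred, raw = predict(model, [[0.0]])
        assert pred[0] == 1
        np.testing.assert_allclose(raw, [[0.5, 0.5]])
        # asymmetric beta -> clear argmax
        model2 = manual_model(np.zeros((2, 1)), np.zeros(2), beta=[[1.8, 0.2], [0.0, 0.0]])
        pred2, raw2 = predict(model2, [[0.0]])
        assert pred2[0] == 1 and raw2[0, 0] > raw2[0, 1]

    def test_dimension_mismatch(self):
        model = manual_model(np.zeros((2, 3)), np.zeros(2))
        with pytest.raises(UsageError):
            predict(model, np.zeros((1, 5)))
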