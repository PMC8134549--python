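"""Extreme learning machine: a single-hidden-layer network trained in closed form.

The input weights ``w_i`` and hidden biases ``b_i`` are drawn once from a
continuous distribution (uniform on [-1, 1]) and never adjusted; with an
infinitely differentiable activation ``g`` (sigmoid by default) the hidden
output matrix ``H[n, i] = g(w_i^T x_n + b_i)`` is then fixed, and training
reduces to the linear least-squares problem ``min_beta ||H beta - T||`` with
one-hot targets ``T``. Its minimal-norm solution is given by the Moore-Penrose
pseudoinverse, ``beta_hat = H^+ T`` (computed by SVD): it attains the smallest
training error, has the smallest norm among the minimizers, and is unique --
there is no iterative search and no local optimum. Prediction takes the argmax
of the raw network outputs ``H beta``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, UsageError

logger = logging.getLogger(__name__)

__all__ = ["ELMModel", "hidden_matrix", "predict", "train_elm"]

ACTIVATIONS = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
}


@dataclass
class ELMModel:
    """Random hidden layer plus pseudoinverse-solved output weights."""

    input_weights: np.ndarray  # n_hidden x n_features (w_i rows)
    biases: np.ndarray  # n_hidden (b_i)
    output_weights: np.ndarray  # n_hidden x n_classes (beta)
    activation: str
    seed: int
    class_labels: np.ndarray  # column -> class id
    class_names: list[str]

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]


def hidden_matrix(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Hidden output matrix ``H[n, i] = g(w_i^T x_n + b_i)`` for samples X (N x p)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise UsageError(
            f"X has {X.shape[1]} features, model expects {model.n_features}"
        )
    g = ACTIVATIONS[model.activation]
    return g(X @ model.input_weights.T + model.biases)


def _one_hot(labels: np.ndarray, class_labels: np.ndarray) -> np.ndarray:
    T = np.zeros((labels.size, class_labels.size))
    col = {int(c): j for j, c in enumerate(class_labels)}
    for n, lab in enumerate(labels):
        T[n, col[int(lab)]] = 1.0
    return T


def train_elm(
    X,
    labels,
    n_hidden: int,
    seed: int,
    activation: str = "sigmoid",
    rcond: float = 1e-12,
    ridge: float = 0.0,
    class_names: list[str] | None = None,
) -> ELMModel:
    """Train an ELM: seeded random hidden layer, ``beta = H^+ T`` via SVD.

    ``ridge`` > 0 switches to the regularized solution
    ``beta = (H^T H + ridge I)^-1 H^T T``; the default 0 is the classic
    pseudoinverse formulation.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if X.size == 0 or labels.size == 0:
        raise UsageError("training data must be non-empty")
    if X.shape[0] != labels.size:
        raise UsageError("one label per training sample required")
    if not np.all(np.isfinite(X)):
        raise DataError("training features contain NaN or inf")
    if n_hidden < 1:
        raise UsageError("n_hidden must be >= 1")
    if activation not in ACTIVATIONS:
        raise UsageError(f"unknown activation {activation!r}")
    if n_hidden > X.shape[0]:
        logger.warning(
            "n_hidden = %d exceeds the %d training samples; the hidden layer "
            "theory recommends n_hidden <= N",
            n_hidden,
            X.shape[0],
        )
    class_labels = np.unique(labels)
    if class_names is None:
        class_names = [f"class{c}" for c in class_labels]
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(n_hidden, X.shape[1]))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    model = ELMModel(
        input_weights=W,
        biases=b,
        output_weights=np.zeros((n_hidden, class_labels.size)),
        activation=activation,
        seed=int(seed),
        class_labels=class_labels,
        class_names=class_names,
    )
    H = hidden_matrix(model, X)
    T = _one_hot(labels, class_labels)
    if ridge > 0.0:
        model.output_weights = np.linalg.solve(
            H.T @ H + ridge * np.eye(n_hidden), H.T @ T
        )
    else:
        model.output_weights = np.linalg.pinv(H, rcond=rcond) @ T
    return model


def predict(model: ELMModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class ids and raw network outputs; argmax ties go to the lowest class."""
    H = hidden_matrix(model, X)
    raw = H @ model.output_weights
    # np.argmax returns the first maximum, i.e. the lowest class column on ties
    pred = model.class_labels[np.argmax(raw, axis=1)]
    return pred, raw
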