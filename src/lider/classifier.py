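"""Deep neural network classifier trained with Adam on cell embeddings.

The network is a four-layer MLP: the embedding feeds two sigmoid hidden
layers (528 and 256 units by default) and a softmax output over the J cell
types, O_1 = sigmoid(W_1 x + b_1), O_2 = sigmoid(W_2 O_1 + b_2),
y_hat = softmax(W_3 O_2 + b_3). Training minimizes the cross-entropy
L = -sum_i sum_j y_ji log y_hat_ji by mini-batch Adam (alpha 1e-3,
beta1 0.9, beta2 0.999, eps 1e-8, batch 256, 1200 epochs by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._nn import glorot_uniform
from .exceptions import (
    DimensionError,
    DivergenceError,
    LabelError,
    ParameterError,
)
from .preprocess import EncodedLabels
from .sdae import EmbeddingMatrix

__all__ = [
    "MLPClassifier",
    "AdamConfig",
    "AdamState",
    "ClassifierTrainConfig",
    "sigmoid",
    "softmax",
    "mlp_forward",
    "cross_entropy_loss",
    "adam_step",
    "train_classifier",
    "predict",
    "save_classifier",
    "load_classifier",
    "DEFAULT_HIDDEN_SIZES",
]

DEFAULT_HIDDEN_SIZES = (528, 256)
_LOG_FLOOR = 1e-12  # clipping floor guarding log(0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Elementwise 1 / (1 + exp(-x)), numerically stable for large |x|."""
    return expit(np.asarray(x, dtype=np.float64))


def softmax(x: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-shift; invariant to adding a constant to logits."""
    x = np.asarray(x, dtype=np.float64)
    shifted = x - x.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class MLPClassifier:
    """Feed-forward classifier weights plus the class vocabulary."""

    layer_weights: list[np.ndarray]
    layer_biases: list[np.ndarray]
    class_names: list[str]
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, (W, b) in enumerate(zip(self.layer_weights, self.layer_biases)):
            if W.shape[1] != b.shape[0]:
                raise DimensionError(f"bias shape mismatch at layer {i}")
            if i > 0 and self.layer_weights[i - 1].shape[1] != W.shape[0]:
                raise DimensionError(f"layer widths do not chain at layer {i}")
        if self.layer_weights[-1].shape[1] != len(self.class_names):
            raise DimensionError("output width does not equal number of classes")

    @property
    def topology(self) -> list[int]:
        return [self.layer_weights[0].shape[0]] + [
            W.shape[1] for W in self.layer_weights
        ]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class AdamConfig:
    alpha: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta1 < 1.0 and 0.0 <= self.beta2 < 1.0):
            raise ParameterError("beta1 and beta2 must lie in [0, 1)")
        if self.alpha <= 0 or self.epsilon <= 0:
            raise ParameterError("alpha and epsilon must be positive")


@dataclass
class AdamState:
    """First/second moment accumulators and the step count t."""

    first_moments: list[np.ndarray]
    second_moments: list[np.ndarray]
    step_count: int = 0

    @classmethod
    def for_params(cls, params: list[np.ndarray]) -> "AdamState":
        return cls(
            first_moments=[np.zeros_like(p) for p in params],
            second_moments=[np.zeros_like(p) for p in params],
        )


@dataclass
class ClassifierTrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 1200
    batch_size: int = 256
    seed: int = 0
    hidden_sizes: tuple[int, ...] = DEFAULT_HIDDEN_SIZES

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ParameterError("learning_rate, epochs, batch_size must be positive")


def mlp_forward(model: MLPClassifier, X: np.ndarray) -> np.ndarray:
    """Forward pass returning n x J class probabilities (rows sum to 1)."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != model.layer_weights[0].shape[0]:
        raise DimensionError(
            f"input width {X.shape[1]} does not match model input "
            f"{model.layer_weights[0].shape[0]}"
        )
    H = X
    for W, b in zip(model.layer_weights[:-1], model.layer_biases[:-1]):
        H = sigmoid(H @ W + b)
    return softmax(H @ model.layer_weights[-1] + model.layer_biases[-1])


def cross_entropy_loss(
    probs: np.ndarray,
    labels: EncodedLabels,
    reduction: str = "total",
) -> float:
    """Cross-entropy between predicted probabilities and one-hot true labels.

    ``reduction="total"`` gives -sum_i sum_j y_ji log y_hat_ji; ``"mean"``
    divides by the number of cells. Probabilities are clipped at 1e-12.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ParameterError("probability rows must sum to 1 within 1e-6")
    idx = labels.indices
    if np.any((idx < 0) | (idx >= probs.shape[1])):
        raise LabelError("label index outside [0, J)")
    picked = np.clip(probs[np.arange(len(idx)), idx], _LOG_FLOOR, 1.0)
    total = float(-np.sum(np.log(picked)))
    if reduction == "total":
        return total
    if reduction == "mean":
        return total / len(idx)
    raise ParameterError(f"unknown reduction {reduction!r}")


def adam_step(
    theta: list[np.ndarray],
    gradients: list[np.ndarray],
    state: AdamState,
    cfg: AdamConfig,
) -> tuple[list[np.ndarray], AdamState]:
    """One Adam update with bias correction; updates theta and state in place.

    t <- t+1; m <- b1 m + (1-b1) g; v <- b2 v + (1-b2) g^2;
    theta <- theta - alpha * (m / (1-b1^t)) / (sqrt(v / (1-b2^t)) + eps).
    """
    for g in gradients:
        if not np.isfinite(g).all():
            raise DivergenceError("non-finite gradient in Adam step")
    state.step_count += 1
    t = state.step_count
    for p, g, m, v in zip(theta, gradients, state.first_moments, state.second_moments):
        m *= cfg.beta1
        m += (1.0 - cfg.beta1) * g
        v *= cfg.beta2
        v += (1.0 - cfg.beta2) * g**2
        m_hat = m / (1.0 - cfg.beta1**t)
        v_hat = v / (1.0 - cfg.beta2**t)
        p -= cfg.alpha * m_hat / (np.sqrt(v_hat) + cfg.epsilon)
    return theta, state


def _classifier_grads(
    Ws: list[np.ndarray],
    bs: list[np.ndarray],
    X: np.ndarray,
    one_hot: np.ndarray,
) -> tuple[list[np.ndarray], float]:
    """Backprop of the batch-mean cross-entropy through sigmoid/softmax layers."""
    n = X.shape[0]
    acts = [X]
    H = X
    for W, b in zip(Ws[:-1], bs[:-1]):
        H = sigmoid(H @ W + b)
        acts.append(H)
    probs = softmax(H @ Ws[-1] + bs[-1])
    picked = np.clip((probs * one_hot).sum(axis=1), _LOG_FLOOR, 1.0)
    loss = float(-np.mean(np.log(picked)))
    delta = (probs - one_hot) / n
    grads: list[np.ndarray] = []
    for i in range(len(Ws) - 1, -1, -1):
        grads.insert(0, delta.sum(axis=0))
        grads.insert(0, acts[i].T @ delta)
        if i > 0:
            delta = (delta @ Ws[i].T) * acts[i] * (1.0 - acts[i])
    return grads, loss


def train_classifier(
    X_embed: EmbeddingMatrix | np.ndarray,
    labels: EncodedLabels,
    cfg: ClassifierTrainConfig | None = None,
    adam: AdamConfig | None = None,
) -> MLPClassifier:
    """Fit the MLP by mini-batch Adam, shuffling every epoch under the seed.

    Per-epoch mean cross-entropy is retained on the returned model's
    ``loss_history``.
    """
    cfg = cfg or ClassifierTrainConfig()
    adam = adam or AdamConfig()
    X = X_embed.values if isinstance(X_embed, EmbeddingMatrix) else np.asarray(X_embed, float)
    if labels.n_classes < 2:
        raise ParameterError("training requires at least 2 classes")
    if X.shape[0] != labels.one_hot.shape[0]:
        raise DimensionError("embedding rows do not match label rows")
    rng = np.random.default_rng(cfg.seed)
    widths = [X.shape[1], *cfg.hidden_sizes, labels.n_classes]
    Ws = [glorot_uniform(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
    bs = [np.zeros(w) for w in widths[1:]]
    params = [*Ws, *bs]
    state = AdamState.for_params(params)
    n = X.shape[0]
    history: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            grads, batch_loss = _classifier_grads(Ws, bs, X[idx], labels.one_hot[idx])
            if not np.isfinite(batch_loss):
                raise DivergenceError("classifier loss became non-finite")
            # params list interleaves as [W..., b...]; grads come interleaved
            # per layer [W_i, b_i] — reorder to match
            g_Ws = grads[0::2]
            g_bs = grads[1::2]
            adam_step(params, [*g_Ws, *g_bs], state, adam)
            epoch_loss += batch_loss * len(idx)
        history.append(epoch_loss / n)
    return MLPClassifier(
        layer_weights=Ws,
        layer_biases=bs,
        class_names=list(labels.class_names),
        loss_history=history,
    )


def predict(
    model: MLPClassifier, X_embed: EmbeddingMatrix | np.ndarray
) -> tuple[list[str], np.ndarray]:
    """Argmax class per cell (ties to the lowest class index) plus probabilities."""
    X = X_embed.values if isinstance(X_embed, EmbeddingMatrix) else np.asarray(X_embed, float)
    probs = mlp_forward(model, X)
    idx = probs.argmax(axis=1)  # argmax returns the first maximal index
    return [model.class_names[i] for i in idx], probs


def save_classifier(model: MLPClassifier, path: str) -> None:
    arrays: dict[str, np.ndarray] = {}
    for i, (W, b) in enumerate(zip(model.layer_weights, model.layer_biases)):
        arrays[f"W_{i}"] = W
        arrays[f"b_{i}"] = b
    meta = {"n_layers": len(model.layer_weights), "class_names": model.class_names}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_classifier(path: str) -> MLPClassifier:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        Ws = [archive[f"W_{i}"] for i in range(meta["n_layers"])]
        bs = [archive[f"b_{i}"] for i in range(meta["n_layers"])]
    return MLPClassifier(layer_weights=Ws, layer_biases=bs, class_names=meta["class_names"])
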