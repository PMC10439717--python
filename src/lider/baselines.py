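"""Comparison methods: PCA+NN, raw-expression NN, and L2 logistic regression.

All baselines consume the same standardized matrices and splits as the main
pipeline so accuracy comparisons are well defined. The PCA+NN baseline fits
principal components on training data only and feeds the scores to the same
MLP classifier used on autoencoder embeddings; the raw NN trains that MLP
directly on standardized expression; logistic regression is multinomial
softmax regression with an L2 penalty, solved by full-batch gradient descent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .classifier import (
    AdamConfig,
    ClassifierTrainConfig,
    predict,
    softmax,
    train_classifier,
)
from .exceptions import ParameterError
from .preprocess import EncodedLabels

__all__ = [
    "PCAModel",
    "LogisticModel",
    "pca_fit_transform",
    "pca_transform",
    "pca_nn_classify",
    "raw_nn_classify",
    "logistic_train",
    "logistic_predict",
]


@dataclass
class PCAModel:
    component_matrix: np.ndarray  # d x k loadings, columns orthonormal
    explained_means: np.ndarray   # length-d centering vector
    n_components: int


@dataclass
class LogisticModel:
    weight_matrix: np.ndarray  # d x J
    bias: np.ndarray           # length J
    l2_strength: float
    class_names: list[str]
    converged: bool = True


def pca_fit_transform(X: np.ndarray, k: int) -> tuple[PCAModel, np.ndarray]:
    """Top-k PCA with a deterministic sign convention.

    Centers by column means and takes the leading right singular vectors; each
    component is flipped so its largest-magnitude loading is positive, making
    scores reproducible across runs and libraries.
    """
    X = np.asarray(X, dtype=np.float64)
    n, d = X.shape
    if not 1 <= k <= min(n, d):
        raise ParameterError(f"k={k} must lie in [1, min(n, d)={min(n, d)}]")
    fitter = PCA(n_components=k, svd_solver="full")
    scores = fitter.fit_transform(X)
    components = fitter.components_.T  # d x k
    for j in range(k):
        lead = np.argmax(np.abs(components[:, j]))
        if components[lead, j] < 0:
            components[:, j] *= -1.0
            scores[:, j] *= -1.0
    model = PCAModel(
        component_matrix=components,
        explained_means=fitter.mean_,
        n_components=k,
    )
    return model, scores


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project new data with the training-set means (no leakage)."""
    return (np.asarray(X, float) - model.explained_means) @ model.component_matrix


def pca_nn_classify(
    X_train: np.ndarray,
    y_train: EncodedLabels,
    X_test: np.ndarray,
    k: int = 1000,
    nn_cfg: ClassifierTrainConfig | None = None,
    adam: AdamConfig | None = None,
) -> tuple[list[str], np.ndarray]:
    """PCA (fit on training data only) followed by the MLP classifier.

    ``k`` defaults to 1000 to mirror the autoencoder embedding width, capped
    at min(n, d).
    """
    k = min(k, min(X_train.shape))
    model, train_scores = pca_fit_transform(X_train, k)
    test_scores = pca_transform(model, X_test)
    clf = train_classifier(train_scores, y_train, nn_cfg, adam)
    return predict(clf, test_scores)


def raw_nn_classify(
    X_train: np.ndarray,
    y_train: EncodedLabels,
    X_test: np.ndarray,
    nn_cfg: ClassifierTrainConfig | None = None,
    adam: AdamConfig | None = None,
) -> tuple[list[str], np.ndarray]:
    """The same MLP trained directly on standardized expression (input width d)."""
    clf = train_classifier(np.asarray(X_train, float), y_train, nn_cfg, adam)
    return predict(clf, np.asarray(X_test, float))


def logistic_train(
    X_train: np.ndarray,
    y_train: EncodedLabels,
    l2_strength: float = 1.0,
    learning_rate: float = 0.5,
    max_iter: int = 5000,
    tol: float = 1e-5,
) -> LogisticModel:
    """Multinomial logistic regression by full-batch gradient descent.

    Minimizes mean softmax cross-entropy plus (l2_strength / 2n) ||W||^2 (the
    per-cell scaling keeps the stated learning rate problem-size-robust without
    changing the penalized optimum's character). Stops when the gradient norm
    falls below ``tol``; warns if it never does.
    """
    X = np.asarray(X_train, dtype=np.float64)
    if y_train.n_classes < 2:
        raise ParameterError("logistic regression requires at least 2 classes")
    n, d = X.shape
    J = y_train.n_classes
    W = np.zeros((d, J))
    b = np.zeros(J)
    Y = y_train.one_hot
    converged = False
    grad_norm = np.inf
    # keep the step stable when the penalty curvature l2/n dominates
    learning_rate = learning_rate / (1.0 + learning_rate * l2_strength / n)
    for _it in range(max_iter):
        probs = softmax(X @ W + b)
        delta = (probs - Y) / n
        g_W = X.T @ delta + (l2_strength / n) * W
        g_b = delta.sum(axis=0)
        grad_norm = float(np.sqrt(np.sum(g_W**2) + np.sum(g_b**2)))
        if grad_norm < tol:
            converged = True
            break
        W -= learning_rate * g_W
        b -= learning_rate * g_b
    if not converged:
        warnings.warn(
            f"logistic regression did not converge; final gradient norm {grad_norm:.3g}",
            stacklevel=2,
        )
    return LogisticModel(
        weight_matrix=W,
        bias=b,
        l2_strength=l2_strength,
        class_names=list(y_train.class_names),
        converged=converged,
    )


def logistic_predict(
    model: LogisticModel, X: np.ndarray
) -> tuple[list[str], np.ndarray]:
    probs = softmax(np.asarray(X, float) @ model.weight_matrix + model.bias)
    idx = probs.argmax(axis=1)
    return [model.class_names[i] for i in idx], probs
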