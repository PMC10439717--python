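"""Accuracy, confusion matrices, the cross-platform protocol, and the
method-comparison harness.

Accuracy is the fraction of exact label matches, (1/n) sum_i delta(y_pred_i,
y_i). The cross-platform protocol trains the full pipeline on one dataset and
tests on another measured on a different platform, after aligning the test
genes to the training gene order; test cells whose true type was never seen in
training are flagged and excluded from accuracy (which would otherwise be
ill-defined for them).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .baselines import logistic_predict, logistic_train, pca_nn_classify, raw_nn_classify
from .exceptions import DimensionError, LabelError, ParameterError
from .io import ExpressionMatrix, LabelSet, align_genes
from .pipeline import PipelineConfig, fit_pipeline
from .preprocess import DataSplit, encode_labels, zscore_transform

__all__ = [
    "EvaluationReport",
    "accuracy",
    "confusion_and_misclassified",
    "cross_platform_evaluate",
    "compare_methods",
]

KNOWN_METHODS = ("lider", "pca_nn", "raw_nn", "lr")


@dataclass
class EvaluationReport:
    accuracy: float
    confusion: np.ndarray | None = None
    class_names: list[str] = field(default_factory=list)
    misclassified: list[tuple[str, str, str]] = field(default_factory=list)
    per_method: dict[str, float] = field(default_factory=dict)
    unseen_label_cells: list[tuple[str, str]] = field(default_factory=list)
    matched_genes: int | None = None
    input_digest: str | None = None


def accuracy(predicted: list[str], true: list[str]) -> float:
    """Fraction of cells whose predicted label equals the true label."""
    if len(predicted) != len(true):
        raise DimensionError("predicted and true label lists differ in length")
    if len(true) == 0:
        raise ParameterError("accuracy undefined for zero cells")
    return float(np.mean([p == t for p, t in zip(predicted, true)]))


def confusion_and_misclassified(
    predicted: list[str],
    true: list[str],
    class_names: list[str],
    cell_ids: list[str],
) -> EvaluationReport:
    """J x J confusion matrix (rows true, columns predicted) plus the list of
    every misclassified cell with its identifiers."""
    if not (len(predicted) == len(true) == len(cell_ids)):
        raise DimensionError("inputs differ in length")
    lookup = {c: i for i, c in enumerate(class_names)}
    for label in (*predicted, *true):
        if label not in lookup:
            raise LabelError(f"label {label!r} not in class_names")
    J = len(class_names)
    confusion = np.zeros((J, J), dtype=np.int64)
    misclassified = []
    for cid, t, p in zip(cell_ids, true, predicted):
        confusion[lookup[t], lookup[p]] += 1
        if t != p:
            misclassified.append((cid, t, p))
    acc = float(np.trace(confusion)) / len(true)
    return EvaluationReport(
        accuracy=acc,
        confusion=confusion,
        class_names=list(class_names),
        misclassified=misclassified,
    )


def cross_platform_evaluate(
    train: tuple[ExpressionMatrix, LabelSet],
    test: tuple[ExpressionMatrix, LabelSet],
    config: PipelineConfig | None = None,
    standardization: str = "per_dataset",
) -> EvaluationReport:
    """Train on one platform, test on another.

    The test matrix is projected onto the training gene order (missing genes
    filled with 0), standardized either with its own moments
    (``per_dataset``) or the training moments (``reference``), embedded and
    classified by the pipeline fitted only on the training dataset.
    """
    if standardization not in ("per_dataset", "reference"):
        raise ParameterError(f"unknown standardization mode {standardization!r}")
    X_train, labels_train = train
    X_test, labels_test = test
    if not set(labels_train.labels) & set(labels_test.labels):
        raise LabelError("train and test label vocabularies do not overlap")
    encoded = encode_labels(labels_train)
    fitted = fit_pipeline(X_train, encoded, config)
    aligned, align_report = align_genes(fitted.train_gene_ids, X_test)
    params = fitted.standardization if standardization == "reference" else None
    predicted, _ = fitted.predict(aligned, params=params)

    known = set(encoded.class_names)
    keep = [i for i, t in enumerate(labels_test.labels) if t in known]
    unseen = [
        (labels_test.cell_ids[i], labels_test.labels[i])
        for i, t in enumerate(labels_test.labels)
        if t not in known
    ]
    report = confusion_and_misclassified(
        [predicted[i] for i in keep],
        [labels_test.labels[i] for i in keep],
        encoded.class_names,
        [labels_test.cell_ids[i] for i in keep],
    )
    report.unseen_label_cells = unseen
    report.matched_genes = align_report.n_matched
    return report


def _digest(X: np.ndarray, split: DataSplit) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(split.train_indices.tobytes())
    h.update(split.test_indices.tobytes())
    return h.hexdigest()[:16]


def compare_methods(
    X: ExpressionMatrix,
    labels: LabelSet,
    split: DataSplit,
    methods: tuple[str, ...] = KNOWN_METHODS,
    config: PipelineConfig | None = None,
    pca_components: int = 1000,
    l2_strength: float = 1.0,
) -> EvaluationReport:
    """Run the selected methods on identical standardized data and split.

    Every method sees the same z-scored matrix and the same train/test index
    sets (their digest is recorded in the report), so the per-method test
    accuracies are directly comparable.
    """
    unknown = set(methods) - set(KNOWN_METHODS)
    if unknown:
        raise ParameterError(f"unknown methods: {sorted(unknown)}")
    config = config or PipelineConfig()
    X_std = X if X.standardized else zscore_transform(X)[0]
    encoded = encode_labels(labels)
    tr, te = split.train_indices, split.test_indices
    values = X_std.values
    enc_train = encode_labels([labels.labels[i] for i in tr])
    true_test = [labels.labels[i] for i in te]
    per_method: dict[str, float] = {}
    for method in methods:
        if method == "lider":
            train_mat = ExpressionMatrix(
                values=values[tr],
                gene_ids=list(X_std.gene_ids),
                cell_ids=[X_std.cell_ids[i] for i in tr],
                standardized=True,
            )
            test_mat = ExpressionMatrix(
                values=values[te],
                gene_ids=list(X_std.gene_ids),
                cell_ids=[X_std.cell_ids[i] for i in te],
                standardized=True,
            )
            fitted = fit_pipeline(train_mat, enc_train, config)
            predicted, _ = fitted.predict(test_mat)
        elif method == "pca_nn":
            predicted, _ = pca_nn_classify(
                values[tr], enc_train, values[te],
                k=pca_components, nn_cfg=config.classifier, adam=config.adam,
            )
        elif method == "raw_nn":
            predicted, _ = raw_nn_classify(
                values[tr], enc_train, values[te],
                nn_cfg=config.classifier, adam=config.adam,
            )
        else:  # lr
            model = logistic_train(values[tr], enc_train, l2_strength=l2_strength)
            predicted, _ = logistic_predict(model, values[te])
        per_method[method] = accuracy(predicted, true_test)
    report = EvaluationReport(
        accuracy=max(per_method.values()),
        class_names=encoded.class_names,
        per_method=per_method,
        input_digest=_digest(values, split),
    )
    return report
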