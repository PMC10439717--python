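"""Standardization, label encoding and train/test splitting.

Expression values are z-scored per gene across cells, f_bar = (f - E(f)) / Std(f),
so that expression levels become comparable across genes before they enter the
autoencoder. Std is the population standard deviation (divide by n). Genes with
zero variance map to 0 instead of being dropped, which keeps the gene dimension
d stable so encoder topologies stated in terms of d remain valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError, DimensionError, ParameterError
from .io import ExpressionMatrix, LabelSet

__all__ = [
    "StandardizationParams",
    "EncodedLabels",
    "DataSplit",
    "zscore_transform",
    "encode_labels",
    "split_train_test",
]


@dataclass
class StandardizationParams:
    """Per-gene moments used for (reference-based) standardization."""

    gene_means: np.ndarray
    gene_stds: np.ndarray
    constant_gene_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.gene_means = np.asarray(self.gene_means, dtype=np.float64)
        self.gene_stds = np.asarray(self.gene_stds, dtype=np.float64)
        if self.gene_means.shape != self.gene_stds.shape:
            raise DimensionError("gene_means and gene_stds differ in length")
        if np.any(self.gene_stds < 0):
            raise ParameterError("gene_stds must be non-negative")
        self.constant_gene_mask = self.gene_stds == 0.0


@dataclass
class EncodedLabels:
    """Sorted-unique class vocabulary with integer and one-hot encodings."""

    class_names: list[str]
    indices: np.ndarray
    one_hot: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def decode(self, indices: np.ndarray) -> list[str]:
        return [self.class_names[int(i)] for i in np.asarray(indices)]


@dataclass
class DataSplit:
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    stratified: bool


def zscore_transform(
    X: ExpressionMatrix,
    params: StandardizationParams | None = None,
) -> tuple[ExpressionMatrix, StandardizationParams]:
    """Z-score each gene across cells; optionally with supplied reference moments.

    When ``params`` is given the stored moments are applied as-is, which is the
    reference-based mode used when a test dataset must live on the training
    dataset's scale. Constant genes (std 0) map to 0.
    """
    if X.standardized:
        raise DataError("matrix is already standardized")
    if not np.isfinite(X.values).all():
        raise DataError("NaN or infinite value in expression matrix")
    if params is None:
        means = X.values.mean(axis=0)
        stds = X.values.std(axis=0)  # population std, ddof=0
        params = StandardizationParams(gene_means=means, gene_stds=stds)
    elif params.gene_means.shape[0] != X.n_genes:
        raise DimensionError(
            f"params describe {params.gene_means.shape[0]} genes, matrix has {X.n_genes}"
        )
    safe_std = np.where(params.constant_gene_mask, 1.0, params.gene_stds)
    values = (X.values - params.gene_means) / safe_std
    values[:, params.constant_gene_mask] = 0.0
    out = ExpressionMatrix(
        values=values,
        gene_ids=list(X.gene_ids),
        cell_ids=list(X.cell_ids),
        standardized=True,
    )
    return out, params


def encode_labels(labels: LabelSet | list[str]) -> EncodedLabels:
    """Map label strings to sorted class names, integer indices and one-hot rows."""
    raw = labels.labels if isinstance(labels, LabelSet) else [str(l) for l in labels]
    if len(raw) == 0:
        raise ParameterError("cannot encode an empty label set")
    class_names = sorted(set(raw))
    lookup = {c: i for i, c in enumerate(class_names)}
    indices = np.array([lookup[l] for l in raw], dtype=np.int64)
    one_hot = np.zeros((len(raw), len(class_names)), dtype=np.float64)
    one_hot[np.arange(len(raw)), indices] = 1.0
    if len(class_names) < 2:
        warnings.warn(
            "only one distinct label present; unusable for classifier training",
            stacklevel=2,
        )
    return EncodedLabels(class_names=class_names, indices=indices, one_hot=one_hot)


def split_train_test(
    n: int,
    labels: EncodedLabels | None = None,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratified: bool = False,
) -> DataSplit:
    """Random (optionally stratified) split with |test| = round(test_fraction * n).

    Stratified splits preserve each class's proportion within one cell; classes
    with fewer than two members go entirely to training with a warning.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ParameterError("test_fraction must lie strictly between 0 and 1")
    if stratified and labels is None:
        raise ParameterError("stratified split requires labels")
    rng = np.random.default_rng(seed)
    if not stratified:
        n_test = int(np.floor(test_fraction * n + 0.5))
        perm = rng.permutation(n)
        test = np.sort(perm[:n_test])
        train = np.sort(perm[n_test:])
    else:
        assert labels is not None
        train_parts, test_parts = [], []
        for k in range(labels.n_classes):
            members = np.flatnonzero(labels.indices == k)
            if members.size < 2:
                warnings.warn(
                    f"class {labels.class_names[k]!r} has fewer than 2 cells; "
                    "placed entirely in training",
                    stacklevel=2,
                )
                train_parts.append(members)
                continue
            n_test_k = int(np.floor(test_fraction * members.size + 0.5))
            perm = rng.permutation(members)
            test_parts.append(perm[:n_test_k])
            train_parts.append(perm[n_test_k:])
        train = np.sort(np.concatenate(train_parts))
        test = np.sort(np.concatenate(test_parts)) if test_parts else np.array([], dtype=np.int64)
    return DataSplit(train_indices=train, test_indices=test, seed=seed, stratified=stratified)
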