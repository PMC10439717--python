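"""End-to-end pipeline: z-score -> SDAE embedding -> MLP classifier.

One ``PipelineConfig`` bundles every stage's settings; a single master seed
derives all module seeds by fixed offsets so one flag controls full
reproducibility (corruption masks, weight init, shuffling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classifier import (
    AdamConfig,
    ClassifierTrainConfig,
    MLPClassifier,
    predict,
    train_classifier,
)
from .io import ExpressionMatrix
from .preprocess import EncodedLabels, StandardizationParams, zscore_transform
from .sdae import (
    DEFAULT_HIDDEN_TOPOLOGY,
    EmbeddingMatrix,
    FinetuneConfig,
    PretrainConfig,
    SDAEModel,
    encode_cells,
    finetune_sdae,
    greedy_pretrain,
)

__all__ = [
    "PipelineConfig",
    "FittedPipeline",
    "fit_pipeline",
    "fast_profile",
    "save_pipeline",
    "load_pipeline",
]

_SEED_MOD = 2**31  # derived seeds stay below 2^31

# fixed offsets deriving stage seeds from the master seed
_PRETRAIN_OFFSET = 1
_FINETUNE_OFFSET = 2
_CLASSIFIER_OFFSET = 3


def _derive(seed: int, offset: int) -> int:
    return (seed * 7919 + offset) % _SEED_MOD


@dataclass
class PipelineConfig:
    """All tunables of the embedding + classification pipeline.

    ``hidden_topology`` lists encoder widths after the input layer; the
    shipped default is the 500-500-2000-1000 encoder. ``seed`` is the master
    seed from which each stage's seed is derived.
    """

    hidden_topology: tuple[int, ...] = DEFAULT_HIDDEN_TOPOLOGY
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)
    classifier: ClassifierTrainConfig = field(default_factory=ClassifierTrainConfig)
    adam: AdamConfig = field(default_factory=AdamConfig)
    seed: int = 0


def fast_profile(seed: int = 0, hidden_topology: tuple[int, ...] = (128, 64)) -> PipelineConfig:
    """Reduced-epoch profile (20/40/200) for desk-scale studies; not the
    shipped full-scale defaults (200/400/1200)."""
    return PipelineConfig(
        hidden_topology=hidden_topology,
        pretrain=PretrainConfig(epochs=20),
        finetune=FinetuneConfig(epochs=40, decay_interval=16),
        classifier=ClassifierTrainConfig(epochs=200, hidden_sizes=(64, 32)),
        seed=seed,
    )


@dataclass
class FittedPipeline:
    """Trained SDAE + classifier plus the standardization of the training data."""

    sdae: SDAEModel
    classifier: MLPClassifier
    standardization: StandardizationParams
    config: PipelineConfig
    train_gene_ids: list[str]

    def embed(
        self, X: ExpressionMatrix, params: StandardizationParams | None = None
    ) -> EmbeddingMatrix:
        """Standardize (per-dataset by default, or with supplied reference
        params) and encode."""
        if not X.standardized:
            X, _ = zscore_transform(X, params)
        return encode_cells(self.sdae, X)

    def predict(
        self, X: ExpressionMatrix, params: StandardizationParams | None = None
    ) -> tuple[list[str], np.ndarray]:
        embedding = self.embed(X, params)
        return predict(self.classifier, embedding)


def fit_pipeline(
    X: ExpressionMatrix,
    labels: EncodedLabels,
    config: PipelineConfig | None = None,
) -> FittedPipeline:
    """Train the full pipeline on one (already label-encoded) dataset.

    Standardizes if needed, greedily pretrains the autoencoder stack,
    fine-tunes the unrolled autoencoder, then trains the classifier on the
    frozen bottleneck embeddings.
    """
    config = config or PipelineConfig()
    if X.standardized:
        std_params = StandardizationParams(
            gene_means=np.zeros(X.n_genes), gene_stds=np.ones(X.n_genes)
        )
        X_std = X
    else:
        X_std, std_params = zscore_transform(X)
    topology = [X.n_genes, *config.hidden_topology]
    model = greedy_pretrain(
        topology, X_std, config.pretrain, seed=_derive(config.seed, _PRETRAIN_OFFSET)
    )
    model, _ = finetune_sdae(
        model, X_std, config.finetune, seed=_derive(config.seed, _FINETUNE_OFFSET)
    )
    embeddings = encode_cells(model, X_std)
    clf_cfg = replace(config.classifier, seed=_derive(config.seed, _CLASSIFIER_OFFSET))
    clf = train_classifier(embeddings, labels, clf_cfg, config.adam)
    return FittedPipeline(
        sdae=model,
        classifier=clf,
        standardization=std_params,
        config=config,
        train_gene_ids=list(X.gene_ids),
    )


def save_pipeline(fitted: FittedPipeline, directory: str) -> None:
    """Persist SDAE and classifier checkpoints plus standardization/gene info."""
    import dataclasses
    import json
    import os

    from .classifier import save_classifier
    from .sdae import save_sdae

    os.makedirs(directory, exist_ok=True)
    save_sdae(fitted.sdae, os.path.join(directory, "sdae.npz"))
    save_classifier(fitted.classifier, os.path.join(directory, "classifier.npz"))
    np.savez(
        os.path.join(directory, "preprocess.npz"),
        gene_means=fitted.standardization.gene_means,
        gene_stds=fitted.standardization.gene_stds,
        gene_ids=np.array(fitted.train_gene_ids, dtype="U"),
    )
    cfg = dataclasses.asdict(fitted.config)
    with open(os.path.join(directory, "config.json"), "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)


def load_pipeline(directory: str) -> FittedPipeline:
    import os

    from .classifier import load_classifier
    from .sdae import load_sdae

    for name in ("sdae.npz", "classifier.npz", "preprocess.npz"):
        if not os.path.exists(os.path.join(directory, name)):
            raise FileNotFoundError(
                f"missing checkpoint {name} in {directory}; run training first"
            )
    sdae = load_sdae(os.path.join(directory, "sdae.npz"))
    clf = load_classifier(os.path.join(directory, "classifier.npz"))
    with np.load(os.path.join(directory, "preprocess.npz")) as arc:
        params = StandardizationParams(
            gene_means=arc["gene_means"], gene_stds=arc["gene_stds"]
        )
        gene_ids = [str(g) for g in arc["gene_ids"]]
    return FittedPipeline(
        sdae=sdae,
        classifier=clf,
        standardization=params,
        config=PipelineConfig(),
        train_gene_ids=gene_ids,
    )
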