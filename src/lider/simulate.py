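"""Deterministic generator of clustered, noisy, batch-distorted expression data.

The generative model mirrors what the supervised pipeline assumes about real
single-cell data: k cell types occupy distinct regions of a low-dimensional
latent space; each cell's latent point maps to gene space through a fixed
random linear map (optionally passed through a smooth elementwise
nonlinearity, so linear methods like PCA become suboptimal); gene-level
Gaussian noise, dropout zeros, and optional per-batch multiplicative gene
factors exp(N(0, sigma)) emulate technical variation and cross-platform
shifts. Values are continuous (post-normalization scale) rather than counts:
the pipeline consumes z-scored data, so count-level realism is unnecessary.

Everything is fully determined by the spec's seed: the same spec yields
bit-identical datasets across runs. Class counts follow the requested
proportions exactly via largest-remainder allocation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ParameterError
from .io import ExpressionMatrix, LabelSet

__all__ = ["SyntheticSpec", "generate_dataset", "make_platform_pair"]


@dataclass
class SyntheticSpec:
    """Generative parameters for a clustered expression dataset.

    ``separation`` scales the pairwise distances between cluster centers in
    latent space (within-cluster spread is 1); ``noise_sd`` is the sd of
    additive gene-level Gaussian noise; ``dropout_rate`` is the probability
    that an entry is zeroed (a technical dropout); ``batch`` configures
    ``n_batches`` with per-gene log-normal factors of sd ``log_fold_sd``.
    """

    n_cells: int = 1200
    n_genes: int = 300
    n_types: int = 5
    latent_dim: int = 10
    separation: float = 5.0
    noise_sd: float = 1.0
    dropout_rate: float = 0.1
    nonlinear: bool = False
    n_batches: int = 1
    batch_log_fold_sd: float = 0.0
    type_proportions: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1:
            raise ParameterError("n_types must be >= 1")
        if self.latent_dim > self.n_genes:
            raise ParameterError("latent_dim must not exceed n_genes")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ParameterError("dropout_rate must lie in [0, 1)")
        if self.separation < 0 or self.noise_sd < 0:
            raise ParameterError("separation and noise_sd must be non-negative")
        if self.type_proportions is not None:
            props = np.asarray(self.type_proportions, float)
            if len(props) != self.n_types or np.any(props < 0):
                raise ParameterError("type_proportions must be non-negative, length k")
            if abs(props.sum() - 1.0) > 1e-9:
                raise ParameterError("type_proportions must sum to 1")


def _allocate_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation: counts sum to n and match proportions exactly."""
    ideal = proportions * n
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    shortfall = n - counts.sum()
    for idx in np.argsort(-remainder)[:shortfall]:
        counts[idx] += 1
    return counts


def _latent_model(spec: SyntheticSpec, rng: np.random.Generator):
    """Cluster centers and the latent-to-gene map, shared across batches/platforms."""
    centers = rng.normal(size=(spec.n_types, spec.latent_dim)) * spec.separation
    gene_map = rng.normal(size=(spec.latent_dim, spec.n_genes)) / np.sqrt(spec.latent_dim)
    return centers, gene_map


def _draw_cells(
    spec: SyntheticSpec,
    centers: np.ndarray,
    gene_map: np.ndarray,
    rng: np.random.Generator,
    n_cells: int,
    cell_prefix: str,
) -> tuple[np.ndarray, list[str], list[str], np.ndarray]:
    props = (
        np.asarray(spec.type_proportions, float)
        if spec.type_proportions is not None
        else np.full(spec.n_types, 1.0 / spec.n_types)
    )
    counts = _allocate_counts(n_cells, props)
    type_idx = np.repeat(np.arange(spec.n_types), counts)
    latent = centers[type_idx] + rng.normal(size=(n_cells, spec.latent_dim))
    signal = latent @ gene_map
    if spec.nonlinear:
        signal = np.tanh(signal) * 3.0  # smooth saturation; PCA cannot invert it
    X = signal + rng.normal(scale=spec.noise_sd, size=signal.shape) if spec.noise_sd else signal.copy()
    batch_assignment = rng.integers(spec.n_batches, size=n_cells)
    if spec.n_batches > 1 or spec.batch_log_fold_sd > 0:
        factors = np.exp(
            rng.normal(scale=spec.batch_log_fold_sd, size=(spec.n_batches, spec.n_genes))
        )
        X = X * factors[batch_assignment]
    if spec.dropout_rate > 0:
        X = X * (rng.random(X.shape) >= spec.dropout_rate)
    cell_ids = [f"{cell_prefix}{i}" for i in range(n_cells)]
    labels = [f"type_{t}" for t in type_idx]
    return X, cell_ids, labels, batch_assignment


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, LabelSet, np.ndarray]:
    """Draw one dataset: (expression, labels, per-cell batch assignment)."""
    rng = np.random.default_rng(spec.seed)
    centers, gene_map = _latent_model(spec, rng)
    X, cell_ids, labels, batches = _draw_cells(
        spec, centers, gene_map, rng, spec.n_cells, "cell_"
    )
    gene_ids = [f"gene_{j}" for j in range(spec.n_genes)]
    matrix = ExpressionMatrix(values=X, gene_ids=gene_ids, cell_ids=cell_ids)
    return matrix, LabelSet(cell_ids=cell_ids, labels=labels), batches


def make_platform_pair(
    spec: SyntheticSpec,
    batch_strength: float,
    overlap_fraction: float = 1.0,
) -> tuple[
    tuple[ExpressionMatrix, LabelSet],
    tuple[ExpressionMatrix, LabelSet],
]:
    """Two datasets sharing clusters and label vocabulary but measured on
    different 'platforms': independent cells, distinct per-gene multiplicative
    factors exp(N(0, batch_strength)) per platform, and optionally only a
    fraction of gene identifiers in common (platform B renames the rest),
    to exercise gene-space alignment.
    """
    if not 0.0 < overlap_fraction <= 1.0:
        raise ParameterError("overlap_fraction must lie in (0, 1]")
    rng = np.random.default_rng(spec.seed)
    centers, gene_map = _latent_model(spec, rng)
    platform_spec = replace(spec, n_batches=1, batch_log_fold_sd=0.0)
    datasets = []
    gene_ids = [f"gene_{j}" for j in range(spec.n_genes)]
    for name in ("A", "B"):
        X, cell_ids, labels, _ = _draw_cells(
            platform_spec, centers, gene_map, rng, spec.n_cells, f"{name}_cell_"
        )
        if batch_strength > 0:
            factors = np.exp(rng.normal(scale=batch_strength, size=spec.n_genes))
            X = X * factors
        ids = list(gene_ids)
        if name == "B" and overlap_fraction < 1.0:
            n_shared = int(round(overlap_fraction * spec.n_genes))
            ids = gene_ids[:n_shared] + [
                f"private_B_gene_{j}" for j in range(spec.n_genes - n_shared)
            ]
        matrix = ExpressionMatrix(values=X, gene_ids=ids, cell_ids=cell_ids)
        datasets.append((matrix, LabelSet(cell_ids=cell_ids, labels=labels)))
    return datasets[0], datasets[1]
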