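"""Stacked denoising autoencoder for learning cell embeddings.

Each denoising autoencoder (DAE) corrupts its input with masking noise
(entries independently zeroed at a fixed rate), encodes it as
H = phi(H_in W_e + b_e) and reconstructs the *clean* input through a decoder.
The reconstruction loss is mean squared error summed over features and
averaged over cells, L = (1/n) sum_i sum_j (Xbar_ij - X_ij)^2.

The stack is trained greedily: DAE 1 learns on the standardized expression,
DAE 2 on the clean hidden representation of DAE 1, and so on; afterwards all
encoders and decoders are unrolled (encoders, then decoders in reverse) into a
single deep autoencoder and fine-tuned jointly on uncorrupted input with a
step-decayed SGD schedule. The bottleneck activations are the cell embedding.

Activations are ReLU throughout except the bottleneck (final encoder) layer
and the final decoder layer, which use tanh. The shipped encoder topology is
d-500-500-2000-1000 with the mirrored 1000-2000-500-500-d decoder; reduced
topologies are supported for small studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from ._nn import MomentumSGD, activate, activate_grad, glorot_uniform
from .exceptions import DimensionError, DivergenceError, ParameterError
from .io import ExpressionMatrix

__all__ = [
    "CorruptionSpec",
    "DAELayer",
    "SDAEModel",
    "PretrainConfig",
    "FinetuneConfig",
    "EmbeddingMatrix",
    "mask_corrupt",
    "dae_apply",
    "reconstruction_loss",
    "pretrain_layer",
    "greedy_pretrain",
    "finetune_sdae",
    "finetune_learning_rate",
    "encode_cells",
    "save_sdae",
    "load_sdae",
    "DEFAULT_HIDDEN_TOPOLOGY",
]

# Encoder widths after the input layer; full topology is [d, *DEFAULT_HIDDEN_TOPOLOGY].
DEFAULT_HIDDEN_TOPOLOGY = (500, 500, 2000, 1000)


@dataclass
class CorruptionSpec:
    """Masking-noise description: each entry is zeroed with probability ``rate``."""

    kind: str = "masking"
    rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind != "masking":
            raise ParameterError(f"unsupported corruption kind {self.kind!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ParameterError("corruption rate must lie in [0, 1]")


@dataclass
class DAELayer:
    """One denoising autoencoder: encoder (in->hidden) and decoder (hidden->in)."""

    encoder_weights: np.ndarray  # (in_dim, hidden_dim)
    encoder_bias: np.ndarray
    decoder_weights: np.ndarray  # (hidden_dim, in_dim)
    decoder_bias: np.ndarray
    encoder_activation: str = "relu"
    decoder_activation: str = "relu"

    def __post_init__(self) -> None:
        in_dim, hidden = self.encoder_weights.shape
        if self.decoder_weights.shape != (hidden, in_dim):
            raise DimensionError(
                "decoder weights must be the transpose shape of encoder weights"
            )
        if self.encoder_bias.shape != (hidden,) or self.decoder_bias.shape != (in_dim,):
            raise DimensionError("bias shapes do not match layer dimensions")

    @property
    def in_dim(self) -> int:
        return self.encoder_weights.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.encoder_weights.shape[1]


@dataclass
class SDAEModel:
    layers: list[DAELayer]
    topology: list[int]
    finetuned: bool = False

    def __post_init__(self) -> None:
        dims = [self.layers[0].in_dim] + [l.hidden_dim for l in self.layers]
        if dims != list(self.topology):
            raise DimensionError(
                f"layer dimensions {dims} do not chain into topology {self.topology}"
            )

    @property
    def embedding_dim(self) -> int:
        return self.topology[-1]


@dataclass
class PretrainConfig:
    """Per-layer pretraining settings (SGD with momentum, masking corruption)."""

    epochs: int = 200
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)
    learning_rate: float = 0.1
    momentum: float = 0.9
    batch_size: int = 256

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ParameterError("pretraining requires epochs >= 1")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")


@dataclass
class FinetuneConfig:
    """Whole-stack fine-tuning: lr(e) = base / factor^floor(e / interval)."""

    epochs: int = 400
    base_learning_rate: float = 0.1
    decay_factor: float = 10.0
    decay_interval: int = 80
    momentum: float = 0.9
    batch_size: int = 256

    def __post_init__(self) -> None:
        if self.decay_factor <= 1.0:
            raise ParameterError("decay_factor must exceed 1")
        if self.decay_interval < 1:
            raise ParameterError("decay_interval must be >= 1")


@dataclass
class EmbeddingMatrix:
    """n x k bottleneck activations, one row per cell."""

    values: np.ndarray
    cell_ids: list[str]

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def mask_corrupt(
    H: np.ndarray, spec: CorruptionSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Independently zero each entry with probability ``spec.rate``.

    The input is never modified; a fresh array is returned. When ``rng`` is
    omitted a generator is built from ``spec.seed`` so the mask is
    reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    keep = rng.random(H.shape) >= spec.rate
    return H * keep


def dae_apply(layer: DAELayer, H_in: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass: hidden = phi_e(H W_e + b_e), recon = phi_d(hidden W_d + b_d)."""
    H_in = np.asarray(H_in, dtype=np.float64)
    if H_in.shape[1] != layer.in_dim:
        raise DimensionError(
            f"input has {H_in.shape[1]} features, layer expects {layer.in_dim}"
        )
    hidden = activate(H_in @ layer.encoder_weights + layer.encoder_bias,
                      layer.encoder_activation)
    recon = activate(hidden @ layer.decoder_weights + layer.decoder_bias,
                     layer.decoder_activation)
    return hidden, recon


def reconstruction_loss(X_clean: np.ndarray, X_recon: np.ndarray) -> float:
    """Squared error summed over features, averaged over cells (the 1/n form)."""
    X_clean = np.asarray(X_clean, dtype=np.float64)
    X_recon = np.asarray(X_recon, dtype=np.float64)
    if X_clean.shape != X_recon.shape:
        raise DimensionError(
            f"shape mismatch {X_clean.shape} vs {X_recon.shape}"
        )
    return float(np.sum((X_clean - X_recon) ** 2) / X_clean.shape[0])


def _init_layer(
    in_dim: int,
    hidden_dim: int,
    encoder_activation: str,
    decoder_activation: str,
    rng: np.random.Generator,
) -> DAELayer:
    return DAELayer(
        encoder_weights=glorot_uniform(in_dim, hidden_dim, rng),
        encoder_bias=np.zeros(hidden_dim),
        decoder_weights=glorot_uniform(hidden_dim, in_dim, rng),
        decoder_bias=np.zeros(in_dim),
        encoder_activation=encoder_activation,
        decoder_activation=decoder_activation,
    )


def _dae_grads(
    layer: DAELayer, H_corrupt: np.ndarray, H_clean: np.ndarray
) -> tuple[list[np.ndarray], float]:
    """Backprop for one DAE on one batch.

    The optimizer minimizes the per-element mean of the reconstruction error (a
    constant multiple of the 1/n loss, leaving the minimizer unchanged) so the
    learning rate behaves consistently across feature counts; the returned loss
    is on the 1/n scale.
    """
    b, d = H_corrupt.shape
    pre_h = H_corrupt @ layer.encoder_weights + layer.encoder_bias
    hidden = activate(pre_h, layer.encoder_activation)
    pre_r = hidden @ layer.decoder_weights + layer.decoder_bias
    recon = activate(pre_r, layer.decoder_activation)
    resid = recon - H_clean
    loss = float(np.sum(resid**2) / b)
    delta_r = (2.0 / (b * d)) * resid * activate_grad(pre_r, recon, layer.decoder_activation)
    g_Wd = hidden.T @ delta_r
    g_bd = delta_r.sum(axis=0)
    delta_h = (delta_r @ layer.decoder_weights.T) * activate_grad(
        pre_h, hidden, layer.encoder_activation
    )
    g_We = H_corrupt.T @ delta_h
    g_be = delta_h.sum(axis=0)
    return [g_We, g_be, g_Wd, g_bd], loss


def pretrain_layer(
    layer: DAELayer,
    H_in: np.ndarray,
    cfg: PretrainConfig,
    rng: np.random.Generator | None = None,
) -> tuple[DAELayer, list[float]]:
    """Train one DAE by mini-batch SGD on corrupt-in/clean-out reconstruction.

    Returns the trained layer (a copy) and the per-epoch training loss on the
    1/n scale. Data order is reshuffled every epoch and corruption masks are
    redrawn per batch, all under ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.corruption.seed)
    H_in = np.asarray(H_in, dtype=np.float64)
    if not np.isfinite(H_in).all():
        raise DivergenceError("non-finite values in pretraining input")
    layer = replace(
        layer,
        encoder_weights=layer.encoder_weights.copy(),
        encoder_bias=layer.encoder_bias.copy(),
        decoder_weights=layer.decoder_weights.copy(),
        decoder_bias=layer.decoder_bias.copy(),
    )
    params = [layer.encoder_weights, layer.encoder_bias,
              layer.decoder_weights, layer.decoder_bias]
    opt = MomentumSGD(params, lr=cfg.learning_rate, momentum=cfg.momentum)
    n = H_in.shape[0]
    history: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_sq = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            clean = H_in[idx]
            corrupt = mask_corrupt(clean, cfg.corruption, rng=rng)
            grads, batch_loss = _dae_grads(layer, corrupt, clean)
            if not np.isfinite(batch_loss):
                raise DivergenceError(
                    "reconstruction loss became non-finite; lower the learning rate"
                )
            opt.step(grads)
            epoch_sq += batch_loss * len(idx)
        history.append(epoch_sq / n)
    return layer, history


def _stack_activations(n_layers: int) -> list[tuple[str, str]]:
    """(encoder, decoder) activation per DAE: ReLU except bottleneck encoder
    (last DAE) and final decoder (first DAE's decoder, which emits gene space)."""
    tags = []
    for l in range(n_layers):
        enc = "tanh" if l == n_layers - 1 else "relu"
        dec = "tanh" if l == 0 else "relu"
        tags.append((enc, dec))
    return tags


def greedy_pretrain(
    topology: list[int],
    X: ExpressionMatrix | np.ndarray,
    cfg: PretrainConfig,
    seed: int = 0,
) -> SDAEModel:
    """Layer-by-layer pretraining: DAE l trains on the clean hidden output of
    DAEs 1..l-1, with masking corruption applied afresh to its own input."""
    topology = [int(t) for t in topology]
    if len(topology) < 2:
        raise ParameterError("topology must list at least input and one hidden width")
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    if values.shape[1] != topology[0]:
        raise DimensionError(
            f"data has {values.shape[1]} genes but topology starts at {topology[0]}"
        )
    seeds = np.random.SeedSequence(seed).spawn(len(topology) - 1)
    tags = _stack_activations(len(topology) - 1)
    layers: list[DAELayer] = []
    H = values
    for l, (in_dim, hidden) in enumerate(zip(topology[:-1], topology[1:])):
        rng = np.random.default_rng(seeds[l])
        layer = _init_layer(in_dim, hidden, *tags[l], rng)
        layer, _ = pretrain_layer(layer, H, cfg, rng=rng)
        layers.append(layer)
        H, _ = dae_apply(layer, H)  # clean (uncorrupted) representation feeds l+1
    return SDAEModel(layers=layers, topology=topology)


def finetune_learning_rate(cfg: FinetuneConfig, epoch: int) -> float:
    """Step schedule lr(e) = base / factor^floor(e / interval)."""
    return cfg.base_learning_rate / cfg.decay_factor ** (epoch // cfg.decay_interval)


def _unrolled_params(model: SDAEModel) -> tuple[list[np.ndarray], list[np.ndarray], list[str]]:
    """Weights, biases and activations of the encoder+reversed-decoder chain."""
    Ws, bs, acts = [], [], []
    for layer in model.layers:
        Ws.append(layer.encoder_weights)
        bs.append(layer.encoder_bias)
        acts.append(layer.encoder_activation)
    for layer in reversed(model.layers):
        Ws.append(layer.decoder_weights)
        bs.append(layer.decoder_bias)
        acts.append(layer.decoder_activation)
    return Ws, bs, acts


def finetune_sdae(
    model: SDAEModel,
    X: ExpressionMatrix | np.ndarray,
    cfg: FinetuneConfig,
    seed: int = 0,
) -> tuple[SDAEModel, list[float]]:
    """Jointly fine-tune the unrolled deep autoencoder on uncorrupted input.

    All encoder layers followed by all decoder layers in reverse order form one
    network of widths ``topology + reversed(topology[:-1])``; all weights are
    updated by mini-batch SGD with momentum under the step-decay schedule.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    model = _copy_model(model)
    Ws, bs, acts = _unrolled_params(model)
    params: list[np.ndarray] = []
    for W, b in zip(Ws, bs):
        params.extend([W, b])
    opt = MomentumSGD(params, lr=cfg.base_learning_rate, momentum=cfg.momentum)
    rng = np.random.default_rng(seed)
    n, d = values.shape
    history: list[float] = []
    for epoch in range(cfg.epochs):
        opt.lr = finetune_learning_rate(cfg, epoch)
        order = rng.permutation(n)
        epoch_sq = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = values[idx]
            grads, batch_loss = _deep_ae_grads(batch, Ws, bs, acts)
            if not np.isfinite(batch_loss):
                raise DivergenceError(
                    "fine-tuning loss became non-finite; lower the learning rate"
                )
            opt.step(grads)
            epoch_sq += batch_loss * len(idx)
        history.append(epoch_sq / n)
    model.finetuned = True
    return model, history


def _deep_ae_grads(
    batch: np.ndarray,
    Ws: list[np.ndarray],
    bs: list[np.ndarray],
    acts: list[str],
) -> tuple[list[np.ndarray], float]:
    b, d = batch.shape
    pres, posts = [], [batch]
    H = batch
    for W, bias, act in zip(Ws, bs, acts):
        pre = H @ W + bias
        H = activate(pre, act)
        pres.append(pre)
        posts.append(H)
    resid = H - batch
    loss = float(np.sum(resid**2) / b)
    delta = (2.0 / (b * d)) * resid * activate_grad(pres[-1], posts[-1], acts[-1])
    grads: list[np.ndarray] = []
    for i in range(len(Ws) - 1, -1, -1):
        grads.insert(0, delta.sum(axis=0))        # bias of layer i
        grads.insert(0, posts[i].T @ delta)       # weights of layer i
        if i > 0:
            delta = (delta @ Ws[i].T) * activate_grad(
                pres[i - 1], posts[i], acts[i - 1]
            )
    return grads, loss


def _copy_model(model: SDAEModel) -> SDAEModel:
    layers = [
        replace(
            l,
            encoder_weights=l.encoder_weights.copy(),
            encoder_bias=l.encoder_bias.copy(),
            decoder_weights=l.decoder_weights.copy(),
            decoder_bias=l.decoder_bias.copy(),
        )
        for l in model.layers
    ]
    return SDAEModel(layers=layers, topology=list(model.topology), finetuned=model.finetuned)


def encode_cells(
    model: SDAEModel,
    X: ExpressionMatrix,
    allow_pretrained_only: bool = False,
) -> EmbeddingMatrix:
    """Deterministic forward pass through the encoder chain (no corruption)."""
    if not model.finetuned and not allow_pretrained_only:
        raise ParameterError(
            "model is not fine-tuned; pass allow_pretrained_only=True to override"
        )
    if X.n_genes != model.topology[0]:
        raise DimensionError(
            f"matrix has {X.n_genes} genes but model expects {model.topology[0]}; "
            "consider align_genes"
        )
    H = X.values
    for layer in model.layers:
        H = activate(H @ layer.encoder_weights + layer.encoder_bias,
                     layer.encoder_activation)
    return EmbeddingMatrix(values=H, cell_ids=list(X.cell_ids))


def save_sdae(model: SDAEModel, path: str, config: dict | None = None) -> None:
    """Persist topology, activation tags and all tensors in one .npz archive."""
    arrays: dict[str, np.ndarray] = {}
    tags = []
    for i, l in enumerate(model.layers):
        arrays[f"We_{i}"] = l.encoder_weights
        arrays[f"be_{i}"] = l.encoder_bias
        arrays[f"Wd_{i}"] = l.decoder_weights
        arrays[f"bd_{i}"] = l.decoder_bias
        tags.append([l.encoder_activation, l.decoder_activation])
    meta = {
        "topology": list(model.topology),
        "finetuned": model.finetuned,
        "activations": tags,
        "config": config or {},
    }
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_sdae(path: str) -> SDAEModel:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        layers = []
        for i, (enc_act, dec_act) in enumerate(meta["activations"]):
            layers.append(
                DAELayer(
                    encoder_weights=archive[f"We_{i}"],
                    encoder_bias=archive[f"be_{i}"],
                    decoder_weights=archive[f"Wd_{i}"],
                    decoder_bias=archive[f"bd_{i}"],
                    encoder_activation=enc_act,
                    decoder_activation=dec_act,
                )
            )
    return SDAEModel(layers=layers, topology=meta["topology"], finetuned=meta["finetuned"])
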