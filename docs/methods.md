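# Methods

## Model

`lider` treats cell-type annotation as supervised learning on a cells × genes
matrix X̄ ∈ R^{n×d}. The model has two stages trained in sequence:

1. **Stacked denoising autoencoder (SDAE).** Each layer is a denoising
   autoencoder: the layer's input is corrupted by masking noise (entries set
   to zero independently with probability 0.2), encoded as
   H = φ(H_in W_e + b_e), decoded back to the input width, and trained to
   reconstruct the *clean* input under the squared-error loss
   L = (1/n) Σ_i Σ_j (X̄_ij − X_ij)². Layers are pretrained greedily — layer
   ℓ sees only the clean hidden output of layers 1..ℓ−1, never
   representations from deeper layers — then the encoders and the decoders in
   reverse order are unrolled into one deep autoencoder and fine-tuned
   jointly on uncorrupted input. The bottleneck activations are the cell
   embedding.
2. **MLP classifier.** Two sigmoid hidden layers and a softmax output over
   the J training cell types, trained with mini-batch Adam on the
   cross-entropy of the frozen embeddings. The classifier does not
   backpropagate into the encoder: the embedding is treated as a fixed
   feature map, which keeps the two stages independently testable and lets
   one embedding serve several classifiers.

Assumptions: cell types occupy separable regions of expression space; the
separation may be nonlinear (hence the autoencoder rather than PCA); and
cross-platform differences are largely per-gene scale/location shifts that
per-gene z-scoring removes.

## Parameters

| parameter | default | meaning |
|---|---|---|
| encoder topology | d–500–500–2000–1000 | layer widths; the 1000-unit bottleneck is the embedding. Reduced topologies (e.g. d–128–64) are appropriate for small matrices — widths exceeding n or d add parameters without information. |
| corruption rate | 0.2 | probability an input entry is zeroed during pretraining |
| pretraining | 200 epochs, SGD lr 0.1, momentum 0.9, batch 256 | per-layer denoising optimization (lr/momentum/batch are this package's choices; see below) |
| fine-tuning | 400 epochs, lr 0.1 ÷ 10 every 80 epochs, momentum 0.9 | joint optimization of the unrolled stack on uncorrupted input |
| classifier | hidden 528/256, Adam α 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-8, batch 256, 1200 epochs | supervised stage |
| split | 80/20 random; stratified 70/30 available | evaluation protocol |
| `fast_profile` | epochs 20/40/200, hidden topology (128, 64) | desk-scale profile used by the test suite and acceptance script; explicitly not the full-scale defaults |

## Numerical choices

- **Loss scaling.** The reconstruction loss is reported in its 1/n form
  (summed over genes, averaged over cells). The optimizer minimizes the
  per-element mean — the same objective divided by the constant d — so that
  the stated learning rate 0.1 behaves uniformly across gene counts. The
  classifier optimizes the per-batch mean cross-entropy for the same reason;
  `cross_entropy_loss` exposes both the total and the mean.
- **Corruption semantics.** The 0.2 "drop ratio" is implemented as input
  masking-to-zero during pretraining (the canonical denoising recipe), not
  connection dropout; fine-tuning uses uncorrupted input.
- **Unstated optimizer details.** Pretraining SGD hyperparameters
  (lr 0.1, momentum 0.9, batch 256) and weight initialization (symmetric
  uniform, fan-based, seed-controlled) are not fixed by the method
  description; these defaults are standard practice and are configurable.
- **Standardization axis.** Per gene across cells (population sd, ddof 0).
  Constant genes map to 0 rather than being dropped, preserving d. Each
  dataset is standardized with its own moments by default; reference-based
  standardization (training moments applied to the test set) is available
  for the cross-platform protocol.
- **Stability.** Sigmoid uses the stable piecewise form; softmax subtracts
  the row maximum; log arguments are clipped at 1e-12. Predicted-class ties
  break to the lowest class index. Adam with β₁ = β₂ = 0 and ε → 0 reduces
  to sign-gradient descent, which the tests use as a limit check.
- **Degenerate inputs.** Single-class label sets are flagged unusable for
  training; classes with fewer than two cells go entirely to the training
  side of a stratified split (with a warning); zero gene overlap between
  datasets raises an alignment error rather than silently filling.
- **Seeding.** A single master seed derives per-stage seeds by fixed affine
  offsets (mod 2³¹); two runs with the same seed produce bit-identical
  corruption masks, initial weights, shuffles, checkpoints and predictions.

## Synthetic data

The generator emulates the structure the method assumes: k cell types are
Gaussian clusters in a latent space (between-center scale `separation`,
within-cluster sd 1), mapped to gene space by a fixed random linear map,
optionally through a saturating elementwise nonlinearity (`nonlinear=True`)
that makes the type boundaries invisible to any linear projection — the
regime where an autoencoder embedding should beat equal-width PCA. Gene-level
Gaussian noise, independent dropout zeros, and per-batch multiplicative
factors exp(N(0, σ)) model technical variation and platform shifts;
`make_platform_pair` draws two cohorts from the same latent model with
distinct platform factors and optionally partially overlapping gene lists.

What it does **not** model: count statistics (library size, negative-binomial
overdispersion, zero inflation tied to expression level), gene–gene
correlation beyond the low-rank map, continuous differentiation trajectories,
or doublets. Passing tests therefore demonstrate that the implementation is
correct and that the method behaves as designed under its own assumptions —
not that it attains any particular accuracy on real tissue atlases.

Class counts follow the requested proportions exactly (largest-remainder
allocation), so tiny fixtures have deterministic composition.

## Study sizes

The test suite and `scripts/acceptance.py` run at desk scale: up to 1200
cells × 300 genes with the d–128–64 encoder and the 20/40/200-epoch fast
profile for end-to-end checks, smaller fixtures for unit tests. These sizes
give stable accuracies (separable data is recovered at ≥ 0.95 held-out
accuracy; chance level is recovered when separation is 0) while keeping the
full suite in the tens of seconds.

## Known limitations

- Accuracies reported on synthetic data do not transfer to real atlases; the
  generator's realism is deliberately limited (above).
- The classifier never fine-tunes the encoder; joint end-to-end training
  might improve accuracy but would couple the stages.
- Gene matching is exact string identity — no symbol/Ensembl resolution —
  so cross-dataset evaluation requires consistent gene naming upstream.
- The in-memory pipeline is dense; very large sparse matrices should be
  subsampled or chunked upstream.
- With tanh at the final decoder layer, reconstructions are bounded to
  (−1, 1) while z-scored inputs are not; this caps the attainable
  reconstruction quality but follows the stated activation scheme (the
  embedding, not the reconstruction, is the product).
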