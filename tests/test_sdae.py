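import numpy as np
import pytest
from scipy.stats import binom

from lider.exceptions import DimensionError, ParameterError
from lider.io import ExpressionMatrix
from lider.preprocess import zscore_transform
from lider.sdae import (
    CorruptionSpec,
    DAELayer,
    FinetuneConfig,
    PretrainConfig,
    dae_apply,
    encode_cells,
    finetune_learning_rate,
    finetune_sdae,
    greedy_pretrain,
    load_sdae,
    mask_corrupt,
    pretrain_layer,
    reconstruction_loss,
    save_sdae,
)


def _random_layer(rng, in_dim=4, hidden=3, enc="relu", dec="linear"):
    return DAELayer(
        encoder_weights=rng.normal(size=(in_dim, hidden)),
        encoder_bias=rng.normal(size=hidden),
        decoder_weights=rng.normal(size=(hidden, in_dim)),
        decoder_bias=rng.normal(size=in_dim),
        encoder_activation=enc,
        decoder_activation=dec,
    )


def _standardized_clusters(n=200, d=20, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=4.0, size=(3, d))
    X = centers[rng.integers(3, size=n)] + rng.normal(size=(n, d))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return X


class TestMaskCorrupt:
    def test_rate_zero_is_identity(self):
        H = np.arange(12.0).reshape(3, 4)
        out = mask_corrupt(H, CorruptionSpec(rate=0.0, seed=1))
        np.testing.assert_array_equal(out, H)

    def test_rate_one_zeroes_everything(self):
        H = np.ones((5, 5))
        out = mask_corrupt(H, CorruptionSpec(rate=1.0, seed=1))
        np.testing.assert_array_equal(out, 0.0)

    def test_masked_fraction_in_binomial_band(self):
        # central 99.9% interval of Binomial(10000, 0.2), computed exactly
        H = np.ones((100, 100))
        out = mask_corrupt(H, CorruptionSpec(rate=0.2, seed=7))
        zeros = int(np.sum(out == 0.0))
        lo = binom.ppf(0.0005, 10000, 0.2)
        hi = binom.ppf(0.9995, 10000, 0.2)
        assert lo <= zeros <= hi

    def test_unmasked_entries_bit_exact_and_input_unmodified(self):
        rng = np.random.default_rng(3)
        H = rng.normal(size=(30, 30))
        H_before = H.copy()
        out = mask_corrupt(H, CorruptionSpec(rate=0.3, seed=9))
        np.testing.assert_array_equal(H, H_before)
        kept = out != 0.0
        np.testing.assert_array_equal(out[kept], H[kept])

    def test_invalid_rate_rejected(self):
        with pytest.raises(ParameterError):
            CorruptionSpec(rate=1.5)

    def test_deterministic_under_seed(self):
        H = np.ones((10, 10))
        a = mask_corrupt(H, CorruptionSpec(rate=0.5, seed=4))
        b = mask_corrupt(H, CorruptionSpec(rate=0.5, seed=4))
        np.testing.assert_array_equal(a, b)


class TestDAEApply:
    def test_zero_weights_give_zero_outputs(self):
        layer = DAELayer(
            encoder_weights=np.zeros((2, 3)),
            encoder_bias=np.zeros(3),
            decoder_weights=np.zeros((3, 2)),
            decoder_bias=np.zeros(2),
            encoder_activation="relu",
            decoder_activation="linear",
        )
        hidden, recon = dae_apply(layer, np.array([[1.0, -1.0]]))
        np.testing.assert_array_equal(hidden, 0.0)
        np.testing.assert_array_equal(recon, 0.0)

    def test_relu_clips_negative_preactivation(self):
        layer = DAELayer(
            encoder_weights=np.array([[1.0]]),
            encoder_bias=np.zeros(1),
            decoder_weights=np.array([[1.0]]),
            decoder_bias=np.zeros(1),
            encoder_activation="relu",
            decoder_activation="linear",
        )
        hidden, _ = dae_apply(layer, np.array([[-2.0]]))
        assert hidden[0, 0] == 0.0

    def test_matches_per_unit_loop_oracle(self):
        rng = np.random.default_rng(5)
        layer = _random_layer(rng, in_dim=4, hidden=3, enc="tanh", dec="relu")
        H_in = rng.normal(size=(5, 4))
        hidden, recon = dae_apply(layer, H_in)
        # brute-force double loop over units
        for i in range(5):
            for k in range(3):
                pre = sum(
                    H_in[i, j] * layer.encoder_weights[j, k] for j in range(4)
                ) + layer.encoder_bias[k]
                assert abs(np.tanh(pre) - hidden[i, k]) < 1e-6
            for j in range(4):
                pre = sum(
                    hidden[i, k] * layer.decoder_weights[k, j] for k in range(3)
                ) + layer.decoder_bias[j]
                assert abs(max(pre, 0.0) - recon[i, j]) < 1e-6

    def test_dimension_mismatch_error(self):
        layer = _random_layer(np.random.default_rng(0))
        with pytest.raises(DimensionError):
            dae_apply(layer, np.ones((2, 7)))


class TestReconstructionLoss:
    def test_identical_is_zero(self):
        X = np.random.default_rng(0).normal(size=(4, 6))
        assert reconstruction_loss(X, X) == 0.0

    def test_hand_evaluated_value(self):
        # averages over cells only: ((1-0)^2 + (2-0)^2) / 1 = 5
        assert reconstruction_loss(np.array([[1.0, 2.0]]), np.array([[0.0, 0.0]])) == 5.0

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(1)
        X, R = rng.normal(size=(3, 5)), rng.normal(size=(3, 5))
        base = reconstruction_loss(X, R)
        doubled = reconstruction_loss(X, X + 2 * (R - X))
        assert doubled == pytest.approx(4 * base, rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            reconstruction_loss(np.ones((2, 2)), np.ones((2, 3)))


class TestPretrainLayer:
    def test_loss_decreases_on_clustered_data(self):
        X = _standardized_clusters()
        rng = np.random.default_rng(0)
        layer = _random_layer(rng, in_dim=20, hidden=8, enc="relu", dec="tanh")
        cfg = PretrainConfig(epochs=20, corruption=CorruptionSpec(rate=0.2), batch_size=64)
        _, history = pretrain_layer(layer, X, cfg, rng=np.random.default_rng(1))
        assert history[-1] < history[0]

    def test_epochs_zero_forbidden(self):
        with pytest.raises(ParameterError):
            PretrainConfig(epochs=0)

    def test_bitwise_determinism(self):
        X = _standardized_clusters(n=60, d=10)
        results = []
        for _ in range(2):
            layer = _random_layer(np.random.default_rng(2), in_dim=10, hidden=4)
            cfg = PretrainConfig(epochs=3, batch_size=16)
            trained, _ = pretrain_layer(layer, X, cfg, rng=np.random.default_rng(3))
            results.append(trained)
        np.testing.assert_array_equal(
            results[0].encoder_weights, results[1].encoder_weights
        )
        np.testing.assert_array_equal(
            results[0].decoder_bias, results[1].decoder_bias
        )


class TestGreedyPretrain:
    def test_activation_assignment_four_layers(self):
        X = _standardized_clusters(n=50, d=12)
        cfg = PretrainConfig(epochs=1, batch_size=32)
        model = greedy_pretrain([12, 8, 6, 5, 4], X, cfg, seed=0)
        assert len(model.layers) == 4
        encs = [l.encoder_activation for l in model.layers]
        decs = [l.decoder_activation for l in model.layers]
        assert encs == ["relu", "relu", "relu", "tanh"]  # tanh only at bottleneck
        assert decs == ["tanh", "relu", "relu", "relu"]  # tanh only at final decoder
        assert model.embedding_dim == 4

    def test_degenerate_single_layer_is_doubly_tanh(self):
        X = _standardized_clusters(n=40, d=10)
        model = greedy_pretrain([10, 4], X, PretrainConfig(epochs=1, batch_size=16), seed=0)
        assert len(model.layers) == 1
        assert model.layers[0].encoder_activation == "tanh"
        assert model.layers[0].decoder_activation == "tanh"

    def test_too_short_topology(self):
        with pytest.raises(ParameterError):
            greedy_pretrain([10], np.ones((5, 10)), PretrainConfig(epochs=1))

    def test_layer_shapes_chain(self):
        X = _standardized_clusters(n=40, d=10)
        model = greedy_pretrain(
            [10, 6, 3], X, PretrainConfig(epochs=1, batch_size=16), seed=1
        )
        dims = [model.layers[0].in_dim] + [l.hidden_dim for l in model.layers]
        assert dims == [10, 6, 3]


class TestFinetune:
    def test_learning_rate_schedule_exact(self):
        cfg = FinetuneConfig()
        lrs = [finetune_learning_rate(cfg, e) for e in (0, 80, 160, 240, 320)]
        assert lrs == [0.1, 0.01, 0.001, 1e-4, 1e-5]

    def test_unrolled_widths_are_palindromic(self):
        X = _standardized_clusters(n=40, d=10)
        model = greedy_pretrain(
            [10, 6, 4], X, PretrainConfig(epochs=1, batch_size=16), seed=0
        )
        from lider.sdae import _unrolled_params

        Ws, _, _ = _unrolled_params(model)
        widths = [Ws[0].shape[0]] + [W.shape[1] for W in Ws]
        assert widths == [10, 6, 4, 6, 10]

    def test_finetuning_reduces_reconstruction_loss(self):
        X = _standardized_clusters(n=150, d=25, seed=4)
        pre_cfg = PretrainConfig(epochs=10, batch_size=64)
        model = greedy_pretrain([25, 12, 6], X, pre_cfg, seed=2)
        cfg = FinetuneConfig(epochs=15, decay_interval=6, batch_size=64)
        tuned, history = finetune_sdae(model, X, cfg, seed=3)
        assert tuned.finetuned
        assert history[-1] <= history[0]

    def test_decay_factor_must_exceed_one(self):
        with pytest.raises(ParameterError):
            FinetuneConfig(decay_factor=1.0)


class TestEncodeCells:
    def _fitted(self, n=80, d=15):
        X = _standardized_clusters(n=n, d=d, seed=6)
        mat = ExpressionMatrix(
            values=X, gene_ids=[f"g{j}" for j in range(d)],
            cell_ids=[f"c{i}" for i in range(n)], standardized=True,
        )
        model = greedy_pretrain(
            [d, 8, 4], X, PretrainConfig(epochs=2, batch_size=32), seed=0
        )
        model, _ = finetune_sdae(model, X, FinetuneConfig(epochs=2, batch_size=32), seed=1)
        return model, mat

    def test_shape_and_tanh_range(self):
        model, mat = self._fitted()
        emb = encode_cells(model, mat)
        assert emb.values.shape == (80, 4)
        assert np.all(np.abs(emb.values) < 1.0)  # bottleneck is tanh

    def test_inference_is_deterministic(self):
        model, mat = self._fitted()
        a = encode_cells(model, mat)
        b = encode_cells(model, mat)
        np.testing.assert_array_equal(a.values, b.values)

    def test_pretrained_only_guard(self):
        X = _standardized_clusters(n=30, d=10)
        mat = ExpressionMatrix(
            values=X, gene_ids=[f"g{j}" for j in range(10)],
            cell_ids=[f"c{i}" for i in range(30)], standardized=True,
        )
        model = greedy_pretrain([10, 4], X, PretrainConfig(epochs=1, batch_size=16), seed=0)
        with pytest.raises(ParameterError):
            encode_cells(model, mat)
        emb = encode_cells(model, mat, allow_pretrained_only=True)
        assert emb.values.shape == (30, 4)

    def test_gene_dimension_mismatch_suggests_alignment(self):
        model, _ = self._fitted()
        bad = ExpressionMatrix(
            values=np.ones((3, 7)), gene_ids=[f"x{j}" for j in range(7)],
            cell_ids=["a", "b", "c"], standardized=True,
        )
        with pytest.raises(DimensionError, match="align_genes"):
            encode_cells(model, bad)


class TestCheckpoint:
    def test_round_trip_is_bit_faithful(self, tmp_path):
        X = _standardized_clusters(n=40, d=10)
        model = greedy_pretrain(
            [10, 6, 3], X, PretrainConfig(epochs=1, batch_size=16), seed=5
        )
        model, _ = finetune_sdae(model, X, FinetuneConfig(epochs=1, batch_size=16), seed=6)
        path = str(tmp_path / "model.npz")
        save_sdae(model, path)
        back = load_sdae(path)
        assert back.topology == model.topology
        assert back.finetuned
        for a, b in zip(model.layers, back.layers):
            np.testing.assert_array_equal(a.encoder_weights, b.encoder_weights)
            np.testing.assert_array_equal(a.decoder_weights, b.decoder_weights)
            assert a.encoder_activation == b.encoder_activation


class TestEndToEndDeterminism:
    def test_same_seed_identical_models(self):
        X = _standardized_clusters(n=60, d=12, seed=8)
        models = []
        for _ in range(2):
            m = greedy_pretrain([12, 6, 3], X, PretrainConfig(epochs=2, batch_size=32), seed=9)
            m, _ = finetune_sdae(m, X, FinetuneConfig(epochs=2, batch_size=32), seed=10)
            models.append(m)
        for a, b in zip(models[0].layers, models[1].layers):
            np.testing.assert_array_equal(a.encoder_weights, b.encoder_weights)
            np.testing.assert_array_equal(a.decoder_bias, b.decoder_bias)
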