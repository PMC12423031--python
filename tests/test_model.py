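"""Fusion model: CNN shapes and equivariance, tokens, training behavior."""

from dataclasses import replace

import numpy as np
import pytest

from olfeeg import Label
from olfeeg.errors import ConfigurationError, StructuralError
from olfeeg.model import (
    FeatureStandardizer,
    FusionConfig,
    FusionModel,
    TrainParams,
    predict_trial,
    train_fusion_model,
)
from olfeeg.nn import softmax


class TestCNNExtract:
    def test_reference_output_shape(self, rng):
        model = FusionModel(FusionConfig(seed=0))
        img = rng.standard_normal((4, 10, 400)).astype(np.float32)
        feats = model.cnn_extract(img)
        assert feats.shape == (10, 128)

    def test_zero_input_rows_identical_across_bands(self):
        model = FusionModel(FusionConfig(seed=1))
        feats = model.cnn_extract(np.zeros((4, 10, 400), dtype=np.float32))
        # band-shared weights: every band sees the same (bias-driven) input
        for row in feats[1:]:
            np.testing.assert_array_equal(row, feats[0])

    def test_band_permutation_equivariance(self, rng):
        model = FusionModel(FusionConfig(seed=2))
        img = rng.standard_normal((4, 10, 400)).astype(np.float32)
        perm = rng.permutation(10)
        feats = model.cnn_extract(img)
        feats_p = model.cnn_extract(img[:, perm])
        np.testing.assert_array_equal(feats_p, feats[perm])

    def test_shape_mismatch_named(self, rng):
        model = FusionModel(FusionConfig(seed=0))
        with pytest.raises(StructuralError, match="expected images"):
            model.cnn_extract(rng.standard_normal((3, 10, 400)))


class TestTokens:
    @pytest.mark.parametrize("j", range(3, 10))
    def test_token_count_law(self, j, rng):
        cfg = FusionConfig(n_bands=j + 1, seed=0)
        model = FusionModel(cfg)
        seq = model.tokenize(
            rng.standard_normal(4).astype(np.float32),
            rng.standard_normal(10).astype(np.float32),
            rng.standard_normal((j + 1, 128)).astype(np.float32),
        )
        assert seq.tokens.shape[0] == 2 + (j + 1)
        assert seq.sources[:2] == ["CSP", "CMTS"]
        assert len([s for s in seq.sources if s.startswith("subband")]) == j + 1

    def test_zero_inputs_give_embeddings_plus_biases(self):
        model = FusionModel(FusionConfig(seed=4))
        seq = model.tokenize(np.zeros(4, np.float32), np.zeros(10, np.float32),
                             np.zeros((10, 128), np.float32))
        expected0 = model.proj_csp.params["b"] + model.embeddings.params["source"][0]
        np.testing.assert_allclose(seq.tokens[0], expected0, atol=1e-7)

    def test_encode_and_classify_scores(self, rng):
        model = FusionModel(FusionConfig(seed=5))
        seq = model.tokenize(
            rng.standard_normal(4).astype(np.float32),
            rng.standard_normal(10).astype(np.float32),
            rng.standard_normal((10, 128)).astype(np.float32),
        )
        scores = model.encode_and_classify(seq)
        assert scores.shape == (3,)
        p = softmax(scores)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_eval_mode_deterministic(self, rng):
        model = FusionModel(FusionConfig(seed=6))
        args = (rng.standard_normal((2, 4, 10, 400)).astype(np.float32),
                rng.standard_normal((2, 4)).astype(np.float32),
                rng.standard_normal((2, 10)).astype(np.float32))
        np.testing.assert_array_equal(model.forward(*args), model.forward(*args))

    def test_band_token_permutation_invariance_without_embeddings(self, rng):
        # mean pooling + attention with no band/source embeddings cannot see
        # token order
        cfg = FusionConfig(seed=7, use_source_embeddings=False,
                           use_band_embeddings=False, dtype="float64")
        model = FusionModel(cfg)
        csp = rng.standard_normal(4)
        cmts = rng.standard_normal(10)
        bands = rng.standard_normal((10, 128))
        perm = rng.permutation(10)
        s1 = model.encode_and_classify(model.tokenize(csp, cmts, bands))
        s2 = model.encode_and_classify(model.tokenize(csp, cmts, bands[perm]))
        np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_head_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            FusionConfig(embed_dim=30, n_heads=4)


class TestTraining:
    def test_loss_decreases_on_separable_features(self, small_fusion_config, rng):
        n = 48
        labels = np.repeat([0, 1, 2], n // 3)
        # strongly separable: class-dependent offsets on every feature source
        imgs = (rng.standard_normal((n, 4, 6, 64)) +
                labels[:, None, None, None]).astype(np.float32)
        csp = (rng.standard_normal((n, 4)) + 2 * labels[:, None]).astype(np.float32)
        cmts = (rng.standard_normal((n, 10)) - labels[:, None]).astype(np.float32)
        for seed in (0, 1, 2):
            model = FusionModel(replace(small_fusion_config, seed=seed))
            tp = TrainParams(epochs=10, batch_size=16, seed=seed)
            res = train_fusion_model(model, imgs, csp, cmts, labels, tp)
            assert res.loss_history[-1] < res.loss_history[0]

    def test_zero_learning_rate_keeps_weights_and_loss(self, small_fusion_config, rng):
        cfg = replace(small_fusion_config, dropout_conv=0.0, dropout_linear=0.0)
        model = FusionModel(cfg)
        params_of = lambda m: {f"{i}.{k}": v.copy()
                               for i, lay in enumerate(m.all_layers)
                               for k, v in lay.params.items()}
        before = params_of(model)
        n = 12
        imgs = rng.standard_normal((n, 4, 6, 64)).astype(np.float32)
        csp = rng.standard_normal((n, 4)).astype(np.float32)
        cmts = rng.standard_normal((n, 10)).astype(np.float32)
        labels = np.arange(n) % 3
        tp = TrainParams(epochs=3, batch_size=12, learning_rate=0.0, seed=0)
        res = train_fusion_model(model, imgs, csp, cmts, labels, tp)
        assert res.loss_history[0] == pytest.approx(res.loss_history[-1], rel=1e-6)
        for k, v in params_of(model).items():
            np.testing.assert_array_equal(v, before[k])

    def test_default_train_params(self):
        tp = TrainParams()
        assert (tp.epochs, tp.batch_size, tp.learning_rate) == (50, 64, 0.001)

    def test_same_seed_same_final_weights(self, small_fusion_config, rng):
        n = 24
        imgs = rng.standard_normal((n, 4, 6, 64)).astype(np.float32)
        csp = rng.standard_normal((n, 4)).astype(np.float32)
        cmts = rng.standard_normal((n, 10)).astype(np.float32)
        labels = np.arange(n) % 3
        tp = TrainParams(epochs=3, batch_size=8, seed=9)
        final = []
        for _ in range(2):
            model = FusionModel(replace(small_fusion_config, seed=13))
            train_fusion_model(model, imgs, csp, cmts, labels, tp)
            final.append(model.get_weights())
        for k in final[0]:
            np.testing.assert_array_equal(final[0][k], final[1][k])


class TestPredictTrial:
    def test_argmax_and_probabilities(self, small_fusion_config, rng):
        model = FusionModel(small_fusion_config)
        feats = {
            "image": rng.standard_normal((4, 6, 64)).astype(np.float32),
            "csp": rng.standard_normal(4).astype(np.float32),
            "cmts": rng.standard_normal(10).astype(np.float32),
        }
        label, probs = predict_trial(model, feats)
        assert probs.shape == (3,)
        assert label == Label(int(np.argmax(probs)))
        label2, probs2 = predict_trial(model, feats)
        np.testing.assert_array_equal(probs, probs2)

    def test_missing_source_rejected(self, small_fusion_config):
        model = FusionModel(small_fusion_config)
        with pytest.raises(StructuralError, match="cmts"):
            predict_trial(model, {"image": np.zeros((4, 6, 64)),
                                  "csp": np.zeros(4)})

    def test_tie_breaks_toward_ad(self):
        # AD is class index 0; argmax resolves exact ties to the lowest index
        probs = np.array([0.4, 0.4, 0.2])
        assert Label(int(np.argmax(probs))) == Label.AD


class TestFeatureStandardizer:
    def test_train_statistics_are_applied(self, rng):
        imgs = rng.standard_normal((20, 2, 3, 16)) * 5 + 3
        csp = rng.standard_normal((20, 4)) * 2 + 1
        cmts = rng.standard_normal((20, 6)) - 4
        sc = FeatureStandardizer().fit(imgs, csp, cmts)
        ti, tc, tm = sc.transform(imgs, csp, cmts)
        np.testing.assert_allclose(ti.mean(axis=(0, 2, 3)), 0.0, atol=1e-10)
        np.testing.assert_allclose(tc.std(axis=0), 1.0, atol=1e-10)
        np.testing.assert_allclose(tm.mean(axis=0), 0.0, atol=1e-10)

    def test_unfitted_rejected(self, rng):
        with pytest.raises(StructuralError):
            FeatureStandardizer().transform(np.zeros((1, 1, 1, 1)),
                                            np.zeros((1, 1)), np.zeros((1, 1)))
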