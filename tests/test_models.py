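"""CNN/ResNet scorers: architecture contracts, optimization, determinism."""

import numpy as np
import pytest

from mirsite import _nn
from mirsite.datasets import LabeledPair
from mirsite.encoding import standardize_mirna, standardize_target
from mirsite.models import (
    CNNConfig,
    ResNetConfig,
    build_cnn,
    build_resnet,
    load_checkpoint,
    predict_scores,
    save_checkpoint,
    train,
)

TOY_CONFIG = CNNConfig(
    conv_channels=(8, 8),
    pools=(2, 2),
    dense_units=(16,),
    dropout_rate=0.0,
    learning_rate=0.01,
)


def separable_pairs(n_per_class):
    """A trivially separable toy set: all-complementary vs. no-complementary."""
    mir = standardize_mirna("A" * 20)
    pos = [
        LabeledPair(mir, standardize_target("U" * 50, id=f"p{i}"), 1.0)
        for i in range(n_per_class)
    ]
    neg = [
        LabeledPair(mir, standardize_target("A" * 50, id=f"n{i}"), 0.0)
        for i in range(n_per_class)
    ]
    return pos + neg


def noisy_separable_pairs(rng, n_per_class):
    """Separable but non-constant: complementary prefix length decides."""
    pairs = []
    for i in range(n_per_class * 2):
        mir_seq = "".join(rng.choice(list("ACGU"), size=20))
        mir = standardize_mirna(mir_seq, id=f"m{i}")
        if i < n_per_class:
            core = "".join({"A": "U", "U": "A", "G": "C", "C": "G"}[b] for b in mir_seq[:12][::-1])
            rest = "".join(rng.choice(list("ACGU"), size=50 - 12))
            tgt = standardize_target(core + rest, id=f"t{i}")
            pairs.append(LabeledPair(mir, tgt, 1.0))
        else:
            tgt = standardize_target("".join(rng.choice(list("ACGU"), size=50)), id=f"t{i}")
            pairs.append(LabeledPair(mir, tgt, 0.0))
    return pairs


class TestBuildCnn:
    def test_default_architecture_shape(self):
        scorer = build_cnn(CNNConfig.desk())
        kinds = [type(l).__name__ for l in scorer.net.layers]
        assert kinds.count("Conv2D") == 6
        assert kinds.count("Dense") == 3  # 2 dense blocks + sigmoid head
        assert scorer.n_parameters > 0

    def test_zero_conv_blocks_rejected(self):
        with pytest.raises(ValueError, match="convolutional block"):
            build_cnn(CNNConfig(conv_channels=(), pools=()))

    def test_excessive_pooling_rejected(self):
        cfg = CNNConfig(conv_channels=(4,) * 6, pools=(2,) * 6)
        with pytest.raises(ValueError, match="footprint"):
            build_cnn(cfg)

    def test_forward_pass_in_unit_interval(self, rng):
        scorer = build_cnn(TOY_CONFIG, seed=1)
        scores = predict_scores(scorer, separable_pairs(2))
        assert scores.shape == (4,)
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_paper_hyperparameters_are_defaults(self):
        cfg = CNNConfig()
        assert (cfg.kernel, cfg.dropout_rate, cfg.learning_rate) == (5, 0.3, 0.00152)
        assert (cfg.epochs, cfg.batch_size) == (10, 32)
        assert len(cfg.conv_channels) == 6 and len(cfg.dense_units) == 2


class TestBuildResnet:
    def test_first_operation_is_residual_stage_not_stem(self):
        scorer = build_resnet(ResNetConfig.desk())
        first = scorer.net.layers[0]
        assert type(first).__name__ == "Residual"
        # no 7x7 convolution anywhere, and no pooling before the first block
        convs = [l for l in scorer.net._flat() if type(l).__name__ == "Conv2D"]
        assert all(c.k != 7 for c in convs)

    def test_forward_in_unit_interval(self):
        scorer = build_resnet(ResNetConfig.desk(), seed=2)
        scores = predict_scores(scorer, separable_pairs(3))
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_learns_two_point_separation(self):
        cfg = ResNetConfig(
            stage_blocks=(1,), stage_channels=(4,), dropout_rate=0.0, learning_rate=0.01
        )
        pairs = separable_pairs(1)
        trained = train(build_resnet(cfg, seed=0), pairs, None, seed=0, epochs=60)
        s = predict_scores(trained, pairs)
        assert s[0] > s[1]


class TestTraining:
    def test_overfits_small_separable_set(self, rng):
        pairs = noisy_separable_pairs(rng, 5)
        trained = train(build_cnn(TOY_CONFIG, seed=0), pairs, None, seed=0, epochs=200)
        assert trained.history["train_loss"][-1] < 0.01

    def test_same_seed_reproduces_validation_loss(self, rng):
        pairs = noisy_separable_pairs(rng, 8)
        val = noisy_separable_pairs(rng, 4)
        runs = [
            train(build_cnn(TOY_CONFIG, seed=5), pairs, val, seed=5, epochs=3)
            for _ in range(2)
        ]
        assert runs[0].history["val_loss"] == runs[1].history["val_loss"]

    def test_constant_soft_labels_calibrate_to_prevalence(self, rng):
        # no-signal limit: every label equals the base rate
        prevalence = 0.3
        pairs = [
            LabeledPair(p.mirna, p.target, prevalence, origin="synthetic")
            for p in noisy_separable_pairs(rng, 20)
        ]
        trained = train(build_cnn(TOY_CONFIG, seed=1), pairs, None, seed=1, epochs=60)
        preds = predict_scores(trained, pairs)
        assert abs(preds.mean() - prevalence) < 0.05

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train(build_cnn(TOY_CONFIG), [], None)


class TestPredictScores:
    def test_empty_input(self):
        assert predict_scores(build_cnn(TOY_CONFIG), []).shape == (0,)

    def test_duplicate_pairs_score_identically(self, rng):
        pairs = noisy_separable_pairs(rng, 3)
        doubled = pairs + pairs
        s = predict_scores(build_cnn(TOY_CONFIG, seed=3), doubled)
        np.testing.assert_allclose(s[: len(pairs)], s[len(pairs) :])

    def test_batch_size_invariance(self, rng):
        pairs = noisy_separable_pairs(rng, 100)
        scorer = build_cnn(TOY_CONFIG, seed=4)
        trained = train(scorer, pairs, None, seed=4, epochs=2)
        s1 = predict_scores(trained, pairs, batch_size=1)
        s256 = predict_scores(trained, pairs, batch_size=256)
        assert np.abs(s1 - s256).max() <= 1e-6


class TestCheckpoint:
    def test_round_trip_preserves_scores(self, tmp_path, rng):
        pairs = noisy_separable_pairs(rng, 6)
        trained = train(build_cnn(TOY_CONFIG, seed=9), pairs, None, seed=9, epochs=3)
        path = tmp_path / "model.npz"
        save_checkpoint(trained, str(path))
        loaded = load_checkpoint(str(path))
        np.testing.assert_allclose(
            predict_scores(trained, pairs), predict_scores(loaded, pairs), atol=1e-7
        )
        assert loaded.config == trained.config
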