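import numpy as np
import pytest

from insound.classifier import (
    AugmentConfig,
    ModelConfig,
    TrainConfig,
    augment,
    build_model,
    count_flops,
    count_parameters,
    default_stage_table,
    eval_transform,
    load_model,
    predict,
    save_model,
    set_freeze_policy,
    train,
)
from insound.nn import Parameter, Tensor, conv2d

RNG = np.random.default_rng(0)
SMALL = ModelConfig(input_size=32)


def small_model(seed=0):
    return build_model(SMALL, seed=seed)


def conv_bn_params(c_in, c_out, k):
    return k * k * c_in * c_out + 2 * c_out


def expected_parameter_total(cfg: ModelConfig) -> int:
    """Independent per-layer arithmetic for the full architecture table."""
    total = 0
    c_in = 3
    for spec in cfg.stages[:-1]:
        if spec.operator == "conv":
            total += conv_bn_params(c_in, spec.filters, 3)
        elif spec.operator == "c3k2":
            c, half = spec.filters, spec.filters // 2
            hidden = int(round(c * spec.channel_reduction))
            total += 2 * conv_bn_params(c_in, half, 1)  # two branch projections
            total += conv_bn_params(half, hidden, 3) + conv_bn_params(hidden, half, 3)
            total += conv_bn_params(2 * half, c, 1)  # fuse
        elif spec.operator == "c2psa":
            c, half = spec.filters, spec.filters // 2
            total += conv_bn_params(c, c, 1)  # cv1
            total += len(cfg.pyramid_scales) * conv_bn_params(half, half, 1)
            total += half * cfg.se_hidden + cfg.se_hidden  # squeeze down
            total += cfg.se_hidden * half + half  # squeeze up
            total += 7 * 7 * 2 * 1 + 1  # spatial gate
            total += conv_bn_params(half, half, 3)  # fuse
            total += conv_bn_params(c, c, 1)  # cv2
        c_in = spec.filters
    total += conv_bn_params(c_in, cfg.head_embed, 1)
    total += cfg.head_embed * cfg.num_classes + cfg.num_classes
    return total


class TestArchitecture:
    def test_stage_table_matches_reference_layout(self):
        table = default_stage_table()
        assert len(table) == 11
        assert [s.filters for s in table] == [16, 32, 64, 64, 128, 128, 128, 256, 256, 256, 12]
        assert [s.operator for s in table[:2]] == ["conv", "conv"]
        assert table[2].channel_reduction == 0.25 and not table[2].residual
        assert table[6].residual and table[8].residual
        assert table[9].operator == "c2psa"

    def test_forward_gives_twelve_probabilities_summing_to_one(self):
        model = small_model()
        probs = predict(model, RNG.random((3, 3, 32, 32), dtype=np.float32))
        assert probs.shape == (3, 12)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_stage_channel_widths(self):
        model = small_model()
        x = Tensor(np.zeros((1, 3, 32, 32), dtype=np.float32))
        model.set_training(False)
        out = model.stages[0](x)
        assert out.shape[1] == 16  # stage 1
        for stage in model.stages[1:8]:
            out = stage(out)
        assert out.shape[1] == 256  # stage 8

    def test_five_stride2_convs_reduce_256_to_8(self):
        model = build_model(ModelConfig(input_size=256))
        model.set_training(False)
        out = Tensor(np.zeros((1, 3, 256, 256), dtype=np.float32))
        for stage in model.stages[:-1]:
            out = stage(out)
        assert out.shape[2] == 256 // 2**5 == 8

    def test_parameter_total_matches_arithmetic_oracle(self):
        cfg = ModelConfig()
        model = build_model(cfg)
        assert count_parameters(model, as_millions=False) == expected_parameter_total(cfg)

    def test_parameter_millions_two_decimals(self):
        assert count_parameters(build_model(ModelConfig())) == 1.54

    def test_single_conv_parameter_arithmetic(self):
        # 3x3 conv 3->16 with bias: 3*3*3*16 + 16 = 448
        w = Parameter(np.zeros((16, 3, 3, 3)))
        b = Parameter(np.zeros(16))
        assert w.data.size + b.data.size == 448

    def test_mismatched_classify_width_rejected(self):
        stages = list(default_stage_table())
        stages[-1] = stages[-1].__class__("classify", 5)
        with pytest.raises(ValueError):
            ModelConfig(stages=tuple(stages))


class TestFlops:
    def test_flops_monotone_in_input_size(self):
        model = small_model()
        small = count_flops(model, 32)
        big = count_flops(model, 64)
        assert big.macs > small.macs
        assert "multiply-accumulate" in big.convention


class TestFreezing:
    def test_freeze_all_removes_every_trainable_parameter(self):
        model = small_model()
        set_freeze_policy(model, 11)
        assert count_parameters(model, as_millions=False) == 0

    def test_freeze_none_keeps_all(self):
        model = small_model()
        n = count_parameters(model, as_millions=False)
        set_freeze_policy(model, 0)
        assert count_parameters(model, as_millions=False) == n

    def test_frozen_stage_weights_unchanged_by_training(self):
        model = small_model(seed=3)
        set_freeze_policy(model, 6)
        before = [p.data.copy() for p in model.stages[0].parameters()]
        X = RNG.random((24, 3, 32, 32), dtype=np.float32)
        y = RNG.integers(0, 12, 24)
        train(model, X, y, TrainConfig(epochs=2, lr=0.05, batch=8, seed=0))
        after = list(model.stages[0].parameters())
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a.data)

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError):
            set_freeze_policy(small_model(), 12)


class TestTraining:
    def test_lr_zero_leaves_parameters_unchanged(self):
        model = small_model(seed=1)
        before = [p.data.copy() for p in model.parameters()]
        X = RNG.random((16, 3, 32, 32), dtype=np.float32)
        y = RNG.integers(0, 12, 16)
        train(model, X, y, TrainConfig(epochs=1, lr=0.0, batch=8, seed=0))
        for b, p in zip(before, model.parameters()):
            np.testing.assert_array_equal(b, p.data)

    def test_same_seed_and_data_give_identical_weights(self):
        X = RNG.random((16, 3, 32, 32), dtype=np.float32)
        y = RNG.integers(0, 12, 16)
        finals = []
        for _ in range(2):
            model = small_model(seed=5)
            train(model, X, y, TrainConfig(epochs=2, lr=0.05, batch=8, seed=5))
            finals.append(np.concatenate([p.data.ravel() for p in model.parameters()]))
        np.testing.assert_array_equal(finals[0], finals[1])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_separable_two_class_toy_loss_drops_90_percent(self, seed):
        """Two visually distinct image classes must be fit almost perfectly."""
        n = 32
        rng = np.random.default_rng(seed)
        X = np.zeros((n, 3, 32, 32), dtype=np.float32)
        y = np.arange(n) % 2
        X[y == 0, :, :16, :] = 1.0  # bright top half
        X[y == 1, :, 16:, :] = 1.0  # bright bottom half
        X += rng.normal(0, 0.05, X.shape).astype(np.float32)
        model = small_model(seed=seed)
        hist = train(model, X, y.astype(int), TrainConfig(epochs=20, lr=0.1, batch=8, seed=seed))
        assert hist["loss"][-1] <= 0.1 * hist["loss"][0]

    def test_history_length_equals_epochs_without_early_stop(self):
        model = small_model()
        X = RNG.random((8, 3, 32, 32), dtype=np.float32)
        y = RNG.integers(0, 12, 8)
        hist = train(model, X, y, TrainConfig(epochs=3, lr=0.01, batch=8, seed=0))
        assert len(hist["loss"]) == 3

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            train(small_model(), np.zeros((0, 3, 32, 32), np.float32), np.zeros(0, int),
                  TrainConfig(epochs=1))


class TestPredict:
    def test_batch_order_invariance(self):
        model = small_model(seed=2)
        X = RNG.random((6, 3, 32, 32), dtype=np.float32)
        p = predict(model, X)
        p_perm = predict(model, X[::-1].copy())
        np.testing.assert_allclose(p_perm, p[::-1], atol=1e-6)

    def test_duplicated_inputs_identical_outputs(self):
        model = small_model(seed=2)
        x = RNG.random((1, 3, 32, 32), dtype=np.float32)
        p = predict(model, np.concatenate([x, x]))
        np.testing.assert_allclose(p[0], p[1], atol=1e-7)

    def test_uint8_hwc_accepted(self):
        model = small_model(seed=2)
        imgs = RNG.integers(0, 255, (2, 32, 32, 3), dtype=np.uint8)
        assert predict(model, imgs).shape == (2, 12)


class TestCheckpoint:
    def test_save_load_round_trip_preserves_predictions(self, tmp_path):
        model = small_model(seed=4)
        X = RNG.random((3, 3, 32, 32), dtype=np.float32)
        p_before = predict(model, X)
        path = str(tmp_path / "ckpt.npz")
        save_model(model, path)
        loaded = load_model(path, SMALL)
        np.testing.assert_allclose(predict(loaded, X), p_before, atol=1e-7)


class TestAugment:
    def test_eval_path_deterministic(self):
        img = RNG.integers(0, 255, (256, 256, 3), dtype=np.uint8)
        a = eval_transform(img, 64)
        b = eval_transform(img, 64)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (3, 64, 64)

    def test_same_seed_same_augmentation(self):
        img = RNG.integers(0, 255, (256, 256, 3), dtype=np.uint8)
        cfg = AugmentConfig(resize=64)
        a = augment(img, cfg, seed=3)
        b = augment(img, cfg, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_output_bounds_and_shape(self):
        img = RNG.integers(0, 255, (256, 256, 3), dtype=np.uint8)
        out = augment(img, AugmentConfig(resize=256), seed=1)
        assert out.shape == (3, 256, 256)
        assert out.min() >= 0.0 and out.max() <= 1.0
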