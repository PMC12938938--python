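"""Architecture: spec validation, shape arithmetic, parameter accounting,
forward-pass contracts, training dynamics, and archive round-trips."""

import numpy as np
import pytest

from exemplarnet import (
    ArchitectureSpec,
    build_model,
    count_parameters,
    forward_logits,
    gap_features,
    load_model,
    save_model,
    stage_shapes,
)
from exemplarnet.architecture import fp32_payload_bytes
from exemplarnet.errors import ConfigurationError, FormatError, InputError
from exemplarnet.nn import Sequential, Residual, BatchNorm2d
from exemplarnet.nn.optim import SGDMomentum, softmax_cross_entropy

SMALL = dict(filters=(8, 16, 32, 64, 48), input_side=32, num_classes=3)


class TestSpecValidation:
    @pytest.mark.parametrize("bad", [
        dict(filters=(96, 192, 384, 768)),             # wrong length
        dict(filters=(96, 192, 384, 768, 0)),          # non-positive
        dict(filters=(96, 200, 400, 800, 1280)),       # does not double
        dict(repetitions=(1, 1, 1, 1)),
        dict(num_classes=1),
        dict(input_side=30),                           # not a multiple of 4
        dict(expansion_factor=0),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            ArchitectureSpec(**bad).validate()

    def test_default_spec_valid(self):
        ArchitectureSpec(num_classes=4).validate()


class TestStageShapes:
    @pytest.mark.parametrize("side,expected", [
        (224, [(56, 96), (28, 192), (14, 384), (7, 768), (7, 1280)]),
        (112, [(28, 96), (14, 192), (7, 384), (3, 768), (3, 1280)]),
        (32, [(8, 96), (4, 192), (2, 384), (1, 768), (1, 1280)]),
    ])
    def test_trace(self, side, expected):
        spec = ArchitectureSpec(input_side=side, num_classes=4)
        assert stage_shapes(spec) == expected

    def test_collapsed_side_rejected(self):
        # 16 px: stem -> 4, downsamples -> 2, 1, then 1 < kernel 2
        with pytest.raises(ConfigurationError):
            stage_shapes(ArchitectureSpec(input_side=16, num_classes=2))

    def test_forward_pass_matches_trace(self, small_model, small_spec, rng):
        """The analytic trace is exact for a real forward pass."""
        x = rng.random((2, 3, 32, 32), dtype=np.float32)
        side, channels = stage_shapes(small_spec)[-1]
        amap = small_model.activation_map(x)
        assert amap.shape == (2, channels, side, side)


class TestParameterCount:
    def test_default_model_rounds_to_7_4_million(self):
        model = build_model(ArchitectureSpec(num_classes=4))
        assert round(count_parameters(model) / 1e6, 1) == 7.4

    def test_isolated_stem_count(self):
        # 4x4x3 conv to 96 with bias plus batch norm scale/shift
        from exemplarnet.nn import Conv2d
        stem = Conv2d(3, 96, kernel=4, stride=4)
        bn = BatchNorm2d(96)
        total = sum(p.size for p in stem.parameters() + bn.parameters())
        assert total == 4 * 4 * 3 * 96 + 96 + 2 * 96 == 4896

    def test_head_grows_by_width_plus_one_per_class(self):
        n2 = count_parameters(build_model(ArchitectureSpec(num_classes=2)))
        n3 = count_parameters(build_model(ArchitectureSpec(num_classes=3)))
        assert n3 - n2 == 1280 + 1

    def test_repetitions_add_blocks_and_parameters(self):
        base = build_model(ArchitectureSpec(**SMALL))
        deeper = build_model(ArchitectureSpec(**{**SMALL,
                                                 "repetitions": (2, 1, 1, 1, 1)}))
        # one extra dual-shortcut block of width 8: 2 * (4*64 + 45*8)
        assert count_parameters(deeper) - count_parameters(base) == 2 * (4 * 64 + 45 * 8)

    def test_expansion_factor_monotonicity(self):
        small = count_parameters(build_model(ArchitectureSpec(**SMALL)))
        wide = count_parameters(build_model(
            ArchitectureSpec(**{**SMALL, "expansion_factor": 8})))
        assert wide > small


class TestForward:
    def test_softmax_probabilities(self, small_model, rng):
        img = rng.random((32, 32, 3), dtype=np.float32)
        probs = forward_logits(small_model, img)
        assert probs.shape == (3,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_inference_determinism(self, small_model, rng):
        img = rng.random((32, 32, 3), dtype=np.float32)
        np.testing.assert_array_equal(forward_logits(small_model, img),
                                      forward_logits(small_model, img))

    def test_shape_mismatch_rejected(self, small_model, rng):
        with pytest.raises(InputError):
            forward_logits(small_model, rng.random((16, 16, 3)))

    def test_gap_equals_explicit_spatial_mean(self, small_model, rng):
        """Oracle: GAP output is the elementwise spatial mean of the final map."""
        img = rng.random((32, 32, 3), dtype=np.float32)
        feats = gap_features(small_model, img)
        amap = small_model.activation_map(img.transpose(2, 0, 1)[None])
        np.testing.assert_allclose(feats, amap[0].mean(axis=(1, 2)), rtol=1e-6)

    def test_gap_length_is_final_width(self, small_model, rng):
        assert gap_features(small_model,
                            rng.random((32, 32, 3))).shape == (48,)


class TestResidualStructure:
    def test_zeroed_subunits_are_identity(self, small_spec, rng):
        """Zeroing every sub-unit weight leaves only the shortcuts: each block
        becomes the identity map on its input."""
        model = build_model(small_spec, seed=0)
        blocks = [l for l in model.trunk.layers if isinstance(l, Residual)]
        assert len(blocks) == 8  # two sub-units per block, four stages
        for block in blocks:
            for p in block.parameters():
                p.value[...] = 0.0
            for layer in block.body.layers:
                if isinstance(layer, BatchNorm2d):
                    layer.running_mean[...] = 0.0
                    layer.running_var[...] = 1.0
        x = rng.random((2, small_spec.filters[0], 8, 8), dtype=np.float32)
        np.testing.assert_allclose(blocks[0].forward(x), x, atol=1e-6)
        np.testing.assert_allclose(blocks[1].forward(x), x, atol=1e-6)

    def test_overfit_one_batch_decreases_loss(self, small_spec, rng):
        """20 gradient steps on one batch strictly decrease the training loss."""
        model = build_model(small_spec, seed=3)
        x = rng.random((8, 3, 32, 32), dtype=np.float32)
        y = np.array([0, 1, 2, 0, 1, 2, 0, 1])
        opt = SGDMomentum(model.parameters(), learning_rate=0.01)
        losses = []
        for _ in range(20):
            logits = model.logits_batch(x, train=True)
            loss, dlogits = softmax_cross_entropy(logits, y)
            losses.append(loss)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
        final, _ = softmax_cross_entropy(model.logits_batch(x, train=True), y)
        assert final < losses[0]


class TestSerialization:
    def test_round_trip_preserves_everything(self, small_spec, rng, tmp_path):
        model = build_model(small_spec, seed=5)
        img = rng.random((32, 32, 3), dtype=np.float32)
        before = forward_logits(model, img)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert count_parameters(loaded) == count_parameters(model)
        assert loaded.spec == model.spec
        np.testing.assert_array_equal(forward_logits(loaded, img), before)

    def test_default_model_payload_rounds_to_28_2_mib(self):
        model = build_model(ArchitectureSpec(num_classes=4))
        assert round(fp32_payload_bytes(model) / 2 ** 20, 1) == 28.2

    def test_truncated_file_raises_format_error(self, small_spec, tmp_path):
        path = tmp_path / "model.npz"
        save_model(build_model(small_spec), path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(FormatError):
            load_model(path)

    def test_wrong_content_raises_format_error(self, tmp_path):
        path = tmp_path / "notamodel.npz"
        np.savez(path, junk=np.arange(3))
        with pytest.raises(FormatError):
            load_model(path)
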