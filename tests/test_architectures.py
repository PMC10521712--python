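"""Network construction: wiring, shapes, parameter counts, checkpoints."""

import numpy as np
import pytest

from joshua_seg.architectures import (ConfigError, ModelSpec,
                                      ResizeRequiredError, build_model,
                                      count_parameters, load_checkpoint,
                                      predict_mask, predict_probabilities,
                                      save_checkpoint)
from joshua_seg.histogram_core import HistogramBlockConfig
from joshua_seg.nn import Tensor
from joshua_seg.nn.layers import AttentionGate, Conv2d, fuse_concat, fuse_multiply

RNG = np.random.default_rng(21)
HIST64 = HistogramBlockConfig(64, 16, 4)
HIST8 = HistogramBlockConfig(8, 4, 2)


def small_spec(variant, base=8, depth=2):
    hist = HistogramBlockConfig(base, 4, base // 4) if "joshua" in variant else None
    return ModelSpec(variant=variant, depth=depth, base_channels=base,
                     histogram=hist)


class TestParameterCounts:
    def test_single_conv_parameter_count(self):
        conv = Conv2d(1, 1, 3, np.random.default_rng(0))
        assert conv.weight.size + conv.bias.size == 10

    def test_multiplicative_fusion_reduces_parameters_about_18_percent(self):
        unet = build_model(ModelSpec("unet"), 0)
        unet_plus = build_model(ModelSpec("unet_plus"), 0)
        ratio = count_parameters(unet_plus) / count_parameters(unet)
        assert ratio == pytest.approx(0.82, abs=0.02)

    def test_histogram_variants_follow_same_reduction(self):
        joshua = build_model(ModelSpec("joshua", histogram=HIST64), 0)
        joshua_plus = build_model(ModelSpec("joshua_plus", histogram=HIST64), 0)
        ratio = count_parameters(joshua_plus) / count_parameters(joshua)
        assert ratio == pytest.approx(0.82, abs=0.02)

    def test_parameter_ordering_across_variants(self):
        counts = {v: count_parameters(build_model(
            ModelSpec(v, histogram=HIST64 if "joshua" in v else None), 0))
            for v in ("unet", "unet_plus", "joshua", "joshua_plus",
                      "attention_unet")}
        assert counts["unet_plus"] < counts["unet"]
        assert counts["joshua_plus"] < counts["joshua"]
        assert counts["joshua"] > counts["unet"]        # histogram params added
        assert counts["attention_unet"] > counts["unet"]

    def test_multiply_variant_halves_decoder_input_channels(self):
        unet = build_model(small_spec("unet", base=8, depth=3), 0)
        plus = build_model(small_spec("unet_plus", base=8, depth=3), 0)
        for blk_cat, blk_mul in zip(unet.ups, plus.ups):
            assert blk_cat.conv1.in_ch == 2 * blk_mul.conv1.in_ch
            assert blk_cat.conv2.out_ch == blk_mul.conv2.out_ch


class TestBuildAndForward:
    @pytest.mark.parametrize("variant", ["unet", "unet_plus", "attention_unet",
                                         "joshua", "joshua_plus"])
    def test_forward_shape_and_open_unit_range(self, variant):
        model = build_model(small_spec(variant), 0)
        out = model(Tensor(np.zeros((1, 3, 32, 48))))
        assert out.shape == (1, 1, 32, 48)
        assert np.all(out.data > 0) and np.all(out.data < 1)

    def test_identical_spec_and_seed_reproduce_parameters(self):
        a = build_model(small_spec("joshua_plus"), 123)
        b = build_model(small_spec("joshua_plus"), 123)
        for (na, pa), (nb, pb) in zip(a.named_parameters(),
                                      b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)
        c = build_model(small_spec("joshua_plus"), 124)
        assert any(not np.array_equal(pa.data, pc.data) for (_, pa), (_, pc)
                   in zip(a.named_parameters(), c.named_parameters()))

    def test_indivisible_input_rejected_not_cropped(self):
        model = build_model(small_spec("unet"), 0)
        with pytest.raises(ResizeRequiredError):
            model(Tensor(np.zeros((1, 3, 30, 32))))

    def test_histogram_config_required_for_joshua(self):
        with pytest.raises(ConfigError, match="histogram"):
            ModelSpec("joshua")

    def test_histogram_bins_must_divide_every_level(self):
        with pytest.raises(ValueError, match="divide"):
            ModelSpec("joshua", depth=2, base_channels=6,
                      histogram=HistogramBlockConfig(4, 4, 1))


class TestFusion:
    def test_concat_stacks_and_round_trips(self):
        a = Tensor(RNG.random((1, 2, 4, 4)))
        d = Tensor(RNG.random((1, 2, 4, 4)))
        cat = fuse_concat(a, d)
        assert cat.shape == (1, 4, 4, 4)
        np.testing.assert_array_equal(cat.narrow(1, 0, 2).data, a.data)
        np.testing.assert_array_equal(cat.narrow(1, 2, 2).data, d.data)

    def test_concat_rejects_spatial_mismatch(self):
        with pytest.raises(ValueError, match="spatial"):
            fuse_concat(Tensor(np.zeros((1, 2, 4, 4))),
                        Tensor(np.zeros((1, 2, 5, 4))))

    def test_multiply_identity_annihilator_and_loop_oracle(self):
        d = Tensor(RNG.random((1, 3, 5, 5)))
        np.testing.assert_array_equal(
            fuse_multiply(Tensor(np.ones((1, 3, 5, 5))), d).data, d.data)
        np.testing.assert_array_equal(
            fuse_multiply(Tensor(np.zeros((1, 3, 5, 5))), d).data, 0.0)
        h = Tensor(RNG.random((1, 3, 5, 5)))
        out = fuse_multiply(h, d).data
        for c in range(3):
            for r in range(5):
                for col in range(5):
                    assert out[0, c, r, col] == pytest.approx(
                        h.data[0, c, r, col] * d.data[0, c, r, col])

    def test_multiply_keeps_channel_count(self):
        h = Tensor(RNG.random((1, 6, 4, 4)))
        assert fuse_multiply(h, Tensor(RNG.random((1, 6, 4, 4)))).shape[1] == 6
        with pytest.raises(ValueError, match="shapes"):
            fuse_multiply(h, Tensor(RNG.random((1, 5, 4, 4))))


class TestAttentionGate:
    def test_zero_weights_give_spatially_constant_coefficients(self):
        gate = AttentionGate(4, np.random.default_rng(0))
        gate.psi.weight.data[:] = 0.0
        gate.psi.bias.data[:] = 0.7
        coeff = gate.coefficients(Tensor(RNG.random((1, 4, 6, 6))),
                                  Tensor(RNG.random((1, 4, 6, 6))))
        expected = 1 / (1 + np.exp(-0.7))
        np.testing.assert_allclose(coeff.data, expected)

    def test_output_is_coefficients_times_encoder(self):
        gate = AttentionGate(3, np.random.default_rng(1))
        enc = Tensor(RNG.random((1, 3, 4, 4)))
        dec = Tensor(RNG.random((1, 3, 4, 4)))
        out = gate(enc, dec)
        coeff = gate.coefficients(enc, dec)
        np.testing.assert_allclose(out.data, coeff.data * enc.data)

    def test_coefficients_bounded_in_open_unit_interval(self):
        # sigmoid output; strictly inside (0, 1) up to float64 rounding,
        # checked at moderate activations where no saturation occurs
        gate = AttentionGate(2, np.random.default_rng(2))
        for trial in range(100):
            rng = np.random.default_rng(trial)
            c = gate.coefficients(Tensor(rng.normal(size=(1, 2, 3, 3))),
                                  Tensor(rng.normal(size=(1, 2, 3, 3))))
            assert np.all(c.data > 0) and np.all(c.data < 1)


class TestPredictMask:
    def test_threshold_tie_break_is_positive(self):
        model = build_model(small_spec("unet"), 0)
        for p in model.parameters():
            p.data[:] = 0.0          # sigmoid(0) = 0.5 everywhere
        img = RNG.random((16, 16, 3))
        assert predict_mask(model, img, threshold=0.5).all()
        assert not predict_mask(model, img, threshold=0.500001).any()

    def test_trained_model_segments_synthetic_blobs(self, smoke_model,
                                                    blob_pairs):
        from joshua_seg.seg_metrics import evaluate_masks
        img, truth = blob_pairs[-1]      # validation image
        mask = predict_mask(smoke_model, img)
        assert evaluate_masks(mask, truth).dice > 0.8


class TestCheckpoints:
    def test_round_trip_preserves_parameters_and_predictions(self, tmp_path):
        model = build_model(small_spec("joshua_plus"), 7)
        img = RNG.random((16, 16, 3))
        before = predict_probabilities(model, img)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert loaded.spec == model.spec
        np.testing.assert_array_equal(predict_probabilities(loaded, img),
                                      before)

    def test_loading_validates_stored_spec(self, tmp_path):
        model = build_model(small_spec("unet"), 0)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert loaded.spec.variant == "unet"
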