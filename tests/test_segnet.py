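"""Network construction, augmentation, training mechanics, ED/ES detection."""

import numpy as np
import pytest

from echoquant import schemes, segnet
from echoquant.nn import UNet, softmax_cross_entropy
from echoquant.phantom import PhantomSpec, generate_cine, generate_geometry, render_bmode
from echoquant.data_io import preprocess_frame
from echoquant.segnet import (
    LVNotFoundError,
    SegModelConfig,
    augment,
    build_model,
    decode_logits,
    desk_config,
    detect_ed_es,
    predict_mask,
    train,
)


class TestBuildModel:
    def test_output_shape_contract(self):
        cfg = desk_config("A2C", "unet", input_size=32)
        model = build_model(cfg)
        out = model.net.forward(np.zeros((2, 1, 32, 32), dtype=np.float32), train=False)
        assert out.shape == (2, cfg.n_classes, 32, 32)

    def test_parameter_count_ordering(self):
        counts = {}
        for arch in segnet.ARCHS:
            cfg = desk_config("A4C", arch, input_size=32)
            counts[arch] = build_model(cfg).net.n_parameters()
        assert counts["dense_unet"] > counts["res_unet"] > counts["unet"]

    def test_minimal_network_runs(self):
        net = UNet("unet", levels=1, base_channels=1, n_classes=2,
                   rng=np.random.default_rng(0))
        out = net.forward(np.zeros((1, 1, 4, 4), dtype=np.float32), train=False)
        assert out.shape == (1, 2, 4, 4)

    def test_indivisible_size_rejected(self):
        with pytest.raises(ValueError):
            SegModelConfig(arch="unet", view="A2C", levels=4, input_size=72)
        net = UNet("unet", levels=3, base_channels=2, n_classes=2)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 1, 36, 36), dtype=np.float32))

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError):
            SegModelConfig(arch="vnet", view="A2C")


class TestAugment:
    def _pair(self):
        spec = PhantomSpec(view="A2C", image_size=64)
        mask = generate_geometry(spec, 0.0)
        img = render_bmode(mask, 1.0, np.random.default_rng(0)).astype(float)
        return img, mask

    def test_zero_probability_is_identity(self):
        img, mask = self._pair()
        out_i, out_m = augment(img, mask, np.random.default_rng(0),
                               flip_prob=0.0, rotation_deg=0.0)
        assert np.array_equal(out_i, img) and np.array_equal(out_m, mask)

    def test_double_flip_is_involution(self):
        img, mask = self._pair()
        once = augment(img, mask, np.random.default_rng(0), flip_prob=1.0, rotation_deg=0.0)
        twice = augment(once[0], once[1], np.random.default_rng(0),
                        flip_prob=1.0, rotation_deg=0.0)
        assert np.array_equal(twice[0], img) and np.array_equal(twice[1], mask)

    def test_labels_stay_in_scheme(self):
        img, mask = self._pair()
        for seed in range(5):
            _, out_m = augment(img, mask, np.random.default_rng(seed))
            assert set(np.unique(out_m)) <= set(np.unique(mask)) | {schemes.BACKGROUND}

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            augment(np.zeros((4, 4)), np.zeros((5, 5)), np.random.default_rng(0))


class TestDecode:
    def test_uniform_scores_all_background(self):
        logits = np.zeros((3, 16, 16), dtype=np.float32)
        assert (decode_logits(logits, "A2C") == schemes.BACKGROUND).all()

    def test_psax_codes_mapped(self):
        logits = np.zeros((3, 4, 4), dtype=np.float32)
        logits[2] = 5.0
        assert (decode_logits(logits, "PSAX") == schemes.MYO).all()

    def test_one_label_per_pixel_within_scheme(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(5, 8, 8)).astype(np.float32)
        out = decode_logits(logits, "A4C")
        assert set(np.unique(out)) <= set(schemes.label_scheme("A4C"))

    def test_perfect_one_hot_gives_dice_one(self):
        from echoquant.agreement import dice

        mask = generate_geometry(PhantomSpec(view="A2C", image_size=64), 0.0)
        codes = schemes.class_codes("A2C")
        logits = np.stack([(mask == c).astype(np.float32) for c in codes])
        pred = decode_logits(logits * 10 - 5, "A2C")
        assert dice(pred, mask, schemes.LV) == 1.0


class TestTraining:
    def _one_sample(self, size=32):
        spec = PhantomSpec(view="A2C", image_size=size)
        mask = generate_geometry(spec, 0.0)
        frame = render_bmode(mask, 1.0, np.random.default_rng(0), spec.pixel_spacing)
        img, _ = preprocess_frame(frame, spec.pixel_spacing, size=size)
        return img.astype(np.float32), mask

    def test_overfit_single_image_reduces_loss(self):
        img, mask = self._one_sample()
        cfg = desk_config("A2C", "unet", input_size=32, epochs=50, augment=False)
        model = build_model(cfg)
        train(model, img[None], mask[None], config=cfg)
        assert model.history[-1]["loss"] < model.history[0]["loss"]

    def test_zero_learning_rate_leaves_weights(self):
        img, mask = self._one_sample()
        cfg = desk_config("A2C", "unet", input_size=32, epochs=2,
                          learning_rate=0.0, augment=False)
        model = build_model(cfg)
        before = [p.v.copy() for p in model.net.params()]
        train(model, img[None], mask[None], config=cfg)
        # trainable weights untouched (BatchNorm running stats may still move)
        for b, a in zip(before, model.net.params()):
            assert np.array_equal(b, a.v)

    def test_empty_training_set_rejected(self):
        cfg = desk_config("A2C", "unet", input_size=32)
        with pytest.raises(ValueError):
            train(build_model(cfg), np.zeros((0, 32, 32)), np.zeros((0, 32, 32)), config=cfg)

    def test_absent_class_warns_but_trains(self):
        img, mask = self._one_sample()
        lv_only = np.where(mask == schemes.LA, 0, mask)  # LA removed
        cfg = desk_config("A2C", "unet", input_size=32, epochs=1, augment=False)
        model = build_model(cfg)
        with pytest.warns(UserWarning, match="absent"):
            train(model, img[None], lv_only[None], config=cfg)

    def test_training_deterministic_per_seed(self):
        img, mask = self._one_sample()
        losses = []
        for _ in range(2):
            cfg = desk_config("A2C", "unet", input_size=32, epochs=3, seed=4)
            model = build_model(cfg)
            train(model, img[None], mask[None], img[None], mask[None], config=cfg)
            losses.append([h["loss"] for h in model.history]
                          + [h["val_dsc"] for h in model.history])
        assert losses[0] == pytest.approx(losses[1], abs=1e-6)

    def test_predict_size_mismatch_rejected(self):
        cfg = desk_config("A2C", "unet", input_size=32)
        with pytest.raises(ValueError):
            predict_mask(build_model(cfg), np.zeros((64, 64), dtype=np.float32))


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        cfg = desk_config("PSAX", "res_unet", input_size=32)
        model = build_model(cfg)
        segnet.save_model(model, tmp_path / "m.npz")
        loaded = segnet.load_model(tmp_path / "m.npz")
        assert loaded.config == cfg
        x = np.random.default_rng(0).random((32, 32)).astype(np.float32)
        assert np.array_equal(predict_mask(model, x), predict_mask(loaded, x))


class TestDetectEdEs:
    def test_phantom_cine_recovers_generator_frames(self):
        _, truth = generate_cine(PhantomSpec(view="A2C", n_frames=8, image_size=96))
        assert detect_ed_es(truth.masks) == (truth.ed_frame, truth.es_frame)

    def test_constant_area_ties_to_first(self):
        mask = generate_geometry(PhantomSpec(view="A2C", image_size=64), 0.0)
        assert detect_ed_es([mask, mask, mask]) == (0, 0)

    def test_monotone_shrinking_area(self):
        spec = PhantomSpec(view="A2C", image_size=96)
        masks = [generate_geometry(spec, p) for p in (0.0, 0.2, 0.4)]
        assert detect_ed_es(masks) == (0, 2)

    def test_lv_absent_named_error(self):
        empty = np.zeros((32, 32), dtype=np.uint8)
        with pytest.raises(LVNotFoundError):
            detect_ed_es([empty, empty])
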