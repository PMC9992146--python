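"""Conditional GAN: losses, architectures, training contracts."""

import numpy as np
import pytest

from cestmrf import nn
from cestmrf.gan import (GanConfig, LossWeights, TrainingPair,
                         build_discriminator, build_feature_extractor,
                         build_generator, composite_loss, normalize_stack,
                         perceptual_loss, reconstruct_volume,
                         retarget_to_direct_quantities, total_variation_loss,
                         train_gan, TrainedGenerator)
from cestmrf.phantom import RawImageStack


class TestTotalVariation:
    def test_constant_image_is_zero(self):
        assert total_variation_loss(np.full((1, 8, 8), 3.7)) == 0.0

    def test_two_by_two_hand_computed(self):
        """[[0,1],[0,1]]: column diffs |1|,|1| mean 1; row diffs 0."""
        img = np.array([[[0.0, 1.0], [0.0, 1.0]]])
        assert total_variation_loss(img) == pytest.approx(1.0)

    def test_positive_homogeneity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 9, 9))
        assert total_variation_loss(4.0 * x) == \
            pytest.approx(4.0 * total_variation_loss(x), rel=1e-6)


class TestPerceptualLoss:
    def test_identical_maps_zero(self):
        ext = build_feature_extractor(GanConfig())
        x = np.random.default_rng(1).normal(size=(2, 16, 16)) \
            .astype(np.float32)
        assert perceptual_loss(x, x, ext) == 0.0

    def test_symmetry(self):
        ext = build_feature_extractor(GanConfig())
        rng = np.random.default_rng(2)
        a = rng.normal(size=(2, 16, 16)).astype(np.float32)
        b = rng.normal(size=(2, 16, 16)).astype(np.float32)
        assert perceptual_loss(a, b, ext) == \
            pytest.approx(perceptual_loss(b, a, ext), rel=1e-5)

    def test_localized_blob_detected(self):
        ext = build_feature_extractor(GanConfig())
        a = np.zeros((2, 16, 16), dtype=np.float32)
        b = a.copy()
        b[:, 6:10, 6:10] = 1.0
        assert perceptual_loss(a, b, ext) > 0


class TestCompositeLoss:
    def test_pure_l1_zero_at_identity(self):
        x = np.random.default_rng(3).normal(size=(2, 8, 8))
        w = LossWeights(lambda1=1, lambda2=0, lambda3=0, lambda4=0)
        total, terms = composite_loss(x, x, None, w)
        assert total == 0.0

    def test_constant_offset_l1(self):
        x = np.zeros((2, 8, 8))
        w = LossWeights(lambda1=1, lambda2=0, lambda3=0, lambda4=0)
        total, _ = composite_loss(x + 0.5, x, None, w)
        assert total == pytest.approx(0.5)

    def test_breakdown_recombines(self):
        rng = np.random.default_rng(4)
        pred = rng.uniform(size=(2, 16, 16)).astype(np.float32)
        target = rng.uniform(size=(2, 16, 16)).astype(np.float32)
        logits = rng.normal(size=(1, 1, 4, 4))
        w = LossWeights(lambda1=100, lambda2=1, lambda3=0.1, lambda4=1)
        ext = build_feature_extractor(GanConfig())
        total, terms = composite_loss(pred, target, logits, w, ext)
        recombined = (w.lambda1 * terms["l1"] + w.lambda2 * terms["adv"]
                      + w.lambda3 * terms["tv"]
                      + w.lambda4 * terms["perceptual"])
        assert abs(total - recombined) <= 1e-9

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            LossWeights(lambda1=-1)
        with pytest.raises(ValueError):
            LossWeights(lambda1=0, lambda2=0, lambda3=0, lambda4=0)


class TestArchitectures:
    def test_generator_shape_contract(self):
        cfg = GanConfig(n_input_channels=9, gen_base_width=8, gen_depth=2,
                        seed=0)
        gen = build_generator(cfg)
        y = gen.forward(np.random.default_rng(5)
                        .normal(size=(1, 9, 64, 64)).astype(np.float32))
        assert y.shape == (1, 2, 64, 64)
        assert np.all((y >= 0) & (y <= 1))

    def test_indivisible_dims_rejected(self):
        cfg = GanConfig(n_input_channels=3, gen_depth=3, seed=0)
        gen = build_generator(cfg)
        with pytest.raises(ValueError, match="divisible"):
            gen.forward(np.zeros((1, 3, 20, 20), dtype=np.float32))

    @pytest.mark.parametrize("depth", [1, 2, 3])
    def test_discriminator_patch_grid(self, depth):
        """Patch logit map is (H, W) / 2**depth by construction."""
        cfg = GanConfig(n_input_channels=5, disc_base_width=8,
                        disc_depth=depth, seed=0)
        disc = build_discriminator(cfg)
        y = disc.forward(np.zeros((2, 7, 32, 32), dtype=np.float32))
        assert y.shape == (2, 1, 32 // 2 ** depth, 32 // 2 ** depth)


def _toy_pairs(n=6, size=16, seed=0, channels=3):
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        x = rng.uniform(size=(channels, size, size)).astype(np.float32)
        t = np.stack([x[:2].mean(axis=0), x[:2].std(axis=0)])
        pairs.append(TrainingPair(
            input_stack=x,
            target_maps=t * np.array([4e-3, 1500.0])[:, None, None]))
    return pairs


class TestTraining:
    def test_determinism_same_seed(self):
        cfg = GanConfig(n_input_channels=3, gen_base_width=4,
                        disc_base_width=4, epochs=2, seed=7, batch_size=2)
        _, log1 = train_gan(_toy_pairs(), cfg, LossWeights())
        _, log2 = train_gan(_toy_pairs(), cfg, LossWeights())
        for col in ("l1", "adv", "tv", "perceptual", "total", "d_loss"):
            assert log1[col].tolist() == log2[col].tolist()

    def test_logged_total_is_weighted_sum(self):
        cfg = GanConfig(n_input_channels=3, gen_base_width=4,
                        disc_base_width=4, epochs=2, seed=7, batch_size=2)
        w = LossWeights()
        _, log = train_gan(_toy_pairs(), cfg, w)
        recomputed = (w.lambda1 * log["l1"] + w.lambda2 * log["adv"]
                      + w.lambda3 * log["tv"]
                      + w.lambda4 * log["perceptual"])
        np.testing.assert_allclose(log["total"], recomputed, atol=1e-9)

    def test_l1_only_leaves_discriminator_untouched(self):
        cfg = GanConfig(n_input_channels=3, gen_base_width=4, epochs=2,
                        seed=7, batch_size=2)
        w = LossWeights(lambda1=1, lambda2=0, lambda3=0, lambda4=0)
        _, log = train_gan(_toy_pairs(), cfg, w)
        assert np.all(log["adv"] == 0) and np.all(log["d_loss"] == 0)

    def test_l1_training_converges_to_median_on_one_pixel(self):
        """With the l1 objective a constant-input model fits the median."""
        rng = np.random.default_rng(8)
        y = rng.uniform(0.2, 0.8, size=(64, 1)).astype(nn.DTYPE)
        x = np.ones((64, 1), dtype=nn.DTYPE)
        lin = nn.Dense(1, 1, rng)
        opt = nn.Adam(lin.params(), lr=5e-3)
        for _ in range(4000):
            lin.zero_grad()
            pred = lin.forward(x)
            _, d = nn.l1_loss(pred, y)
            lin.backward(d)
            opt.step()
        fitted = lin.forward(x[:1]).item()
        assert fitted == pytest.approx(float(np.median(y)), abs=0.01)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_gan([], GanConfig(n_input_channels=3), LossWeights())

    def test_early_stopping_restores_best(self):
        cfg = GanConfig(n_input_channels=3, gen_base_width=4,
                        disc_base_width=4, epochs=30, seed=2, batch_size=2,
                        early_stopping_patience=3)
        gen, log = train_gan(_toy_pairs(10), cfg, LossWeights())
        best = int(log.attrs["best_epoch"])
        assert log["val_l1"].iloc[best] == log["val_l1"].min()


class TestInference:
    def _trained(self):
        cfg = GanConfig(n_input_channels=3, gen_base_width=4,
                        disc_base_width=4, epochs=2, seed=3, batch_size=2)
        gen, _ = train_gan(_toy_pairs(), cfg, LossWeights())
        return gen

    def test_single_slice_and_determinism(self):
        gen = self._trained()
        stack = RawImageStack(images=np.random.default_rng(5)
                              .uniform(0.5, 1, size=(3, 16, 16)))
        maps1, valid = reconstruct_volume(gen, stack)
        maps2, _ = reconstruct_volume(gen, stack)
        assert maps1["volume_fraction"].shape == (16, 16)
        np.testing.assert_array_equal(maps1["exchange_rate"],
                                      maps2["exchange_rate"])
        assert valid.all()

    def test_volume_slicewise(self):
        gen = self._trained()
        vol = np.random.default_rng(6).uniform(0.5, 1, size=(3, 16, 16, 4))
        maps, valid = reconstruct_volume(gen, RawImageStack(images=vol))
        assert maps["volume_fraction"].shape == (16, 16, 4)

    def test_channel_mismatch_rejected(self):
        gen = self._trained()
        with pytest.raises(ValueError, match="images"):
            reconstruct_volume(gen, RawImageStack(images=np.ones((5, 16, 16))))

    def test_outputs_respect_ranges(self):
        gen = self._trained()
        stack = RawImageStack(images=np.random.default_rng(7)
                              .uniform(0.5, 1, size=(3, 16, 16)))
        maps, _ = reconstruct_volume(gen, stack)
        lo, hi = gen.config.output_ranges["exchange_rate"]
        assert np.all((maps["exchange_rate"] >= lo)
                      & (maps["exchange_rate"] <= hi))


class TestNormalizeStack:
    def test_reference_division_and_clip(self):
        imgs = np.stack([np.full((4, 4), 2.0), np.full((4, 4), 1.0),
                         np.full((4, 4), 9.0)])
        out = normalize_stack(imgs, clip=2.0)
        assert np.all(out[0] == 1.0)
        assert np.all(out[1] == 0.5)
        assert np.all(out[2] == 2.0)   # clipped

    def test_background_zeroed(self):
        imgs = np.zeros((3, 4, 4))
        imgs[:, 1, 1] = [1.0, 0.5, 0.25]
        out = normalize_stack(imgs)
        assert out[1, 1, 1] == 0.5
        assert np.all(out[:, 0, 0] == 0.0)


class TestRetargeting:
    def test_targets_and_ranges_swapped(self):
        pairs = _toy_pairs(2)
        aux = [{"concentration": np.full((16, 16), 50.0),
                "pH": np.full((16, 16), 5.2)} for _ in pairs]
        new_pairs, new_cfg = retarget_to_direct_quantities(
            pairs, aux, GanConfig(n_input_channels=3))
        assert new_pairs[0].target_names == ("concentration", "pH")
        assert np.all(new_pairs[0].target_maps[1] == 5.2)
        assert new_cfg.output_ranges["pH"][1] >= 7.0

    def test_missing_aux_rejected(self):
        pairs = _toy_pairs(1)
        with pytest.raises(ValueError, match="aux"):
            retarget_to_direct_quantities(pairs, [{}],
                                          GanConfig(n_input_channels=3))
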