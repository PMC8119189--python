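"""U-Net building blocks: losses, weight maps, augmentation, splitting,
architecture contracts and postprocessing."""

import numpy as np
import pytest

from conftest import mini_cohort_spec
from podoseg.evaluation import dice_pixel
from podoseg.imaging import label_objects
from podoseg.synthetic import simulate_cohort
from podoseg.unet import (DualUNet, LossConfig, ProbabilityPair, TrainConfig,
                          UNetSpec, augment, balanced_dual_loss, bce,
                          build_dual_unet, class_balance_map,
                          compute_weight_map, load_checkpoint, postprocess,
                          predict, save_checkpoint, split_by_subject)


class TestBce:
    def test_perfect_prediction_clipped(self):
        v = bce(np.ones((4, 4)), np.ones((4, 4)))
        assert v == pytest.approx(-np.log(1 - 1e-7), rel=1e-6)
        assert v == pytest.approx(1.0000001e-7, rel=1e-3)

    def test_uniform_half(self):
        y = np.array([1.0, 0.0])
        assert bce(y, np.full(2, 0.5)) == pytest.approx(0.693147, abs=1e-6)

    def test_confident_wrong_prediction(self):
        v = bce(np.ones((2, 2)), np.zeros((2, 2)))
        assert v == pytest.approx(-np.log(1e-7), rel=1e-9)
        assert v == pytest.approx(16.118, abs=1e-3)

    def test_matches_independent_scalar_implementation(self, rng):
        eps = 1e-7
        for _ in range(5):
            y = (rng.random(1000) > 0.5).astype(float)
            p = rng.random(1000)
            ours = bce(y, p, eps)
            pc = np.minimum(np.maximum(p, eps), 1 - eps)
            ref = float(np.mean([-(yi * np.log(pi) + (1 - yi)
                                   * np.log(1 - pi))
                                 for yi, pi in zip(y, pc)]))
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_tensor_path_matches_numpy_path(self, rng):
        from podoseg.nn import Tensor
        y = (rng.random((2, 8, 8, 1)) > 0.5).astype(np.float32)
        p = rng.random((2, 8, 8, 1)).astype(np.float32)
        w = (rng.random((2, 8, 8, 1)) + 0.5).astype(np.float32)
        t = bce(y, Tensor(p), weights=w)
        n = bce(y, p, weights=w)
        assert t.item() == pytest.approx(n, rel=1e-5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            bce(np.zeros((2, 2)), np.zeros((3, 3)))


class TestBalancedDualLoss:
    def test_equal_terms_give_mean(self):
        assert balanced_dual_loss(0.7, 0.7) == pytest.approx(0.7)

    def test_poorer_task_weighted_up(self):
        assert balanced_dual_loss(3.0, 1.0) == pytest.approx(2.5)

    def test_degenerate_single_task(self):
        assert balanced_dual_loss(2.0, 0.0) == pytest.approx(2.0)
        assert balanced_dual_loss(0.0, 0.0) == 0.0

    def test_bounded_between_inputs(self, rng):
        for _ in range(100):
            a, b = rng.random(2) * 5
            val = balanced_dual_loss(a, b)
            assert min(a, b) - 1e-12 <= val <= max(a, b) + 1e-12

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            balanced_dual_loss(-0.1, 1.0)


class TestWeightMap:
    def test_single_object_reduces_to_class_map(self):
        mask = np.zeros((32, 32))
        mask[10:15, 10:15] = 1
        wm = compute_weight_map(mask, w0=10.0, sigma_px=5.0)
        assert np.allclose(wm.w, class_balance_map(mask))

    def test_w0_zero_reduces_to_class_map(self, rng):
        mask = rng.random((32, 32)) > 0.8
        wm = compute_weight_map(mask, w0=0.0)
        assert np.allclose(wm.w, class_balance_map(mask))

    def test_between_two_objects_reference_value(self):
        # two 1-px objects with a background pixel exactly 1 px from each
        mask = np.zeros((9, 9))
        mask[4, 3] = 1
        mask[4, 5] = 1
        wm = compute_weight_map(mask, w0=10.0, sigma_px=5.0)
        wc = class_balance_map(mask)
        expected = wc[4, 4] + 10.0 * np.exp(-4.0 / 50.0)
        assert wm.w[4, 4] == pytest.approx(expected, rel=1e-6)
        assert wm.w[4, 4] - wc[4, 4] == pytest.approx(9.231, abs=1e-3)

    def test_class_map_mean_one_and_inverse_frequency(self):
        mask = np.zeros((10, 10))
        mask[:2] = 1                        # 20% foreground
        wc = class_balance_map(mask, floor=0.01)
        assert wc.mean() == pytest.approx(1.0)
        assert wc[0, 0] == pytest.approx(1 / 0.4)
        assert wc[9, 9] == pytest.approx(1 / 1.6)


@pytest.fixture(scope="module")
def aug_sample():
    samples, _ = simulate_cohort(mini_cohort_spec())
    return samples[0]


class TestAugment:
    def test_identity_transform(self, aug_sample):
        sample = aug_sample
        out = augment(sample, TrainConfig(epochs=1),
                      transform=(False, False, 0.0, 0.0, 0.0))
        assert np.array_equal(out.image.pixels, sample.image.pixels)
        assert np.array_equal(out.masks.podo, sample.masks.podo)

    def test_flip_involution(self, aug_sample):
        sample = aug_sample
        t = (True, False, 0.0, 0.0, 0.0)
        cfg = TrainConfig(epochs=1)
        once = augment(sample, cfg, transform=t)
        twice = augment(once, cfg, transform=t)
        assert np.array_equal(twice.image.pixels, sample.image.pixels)
        assert np.array_equal(twice.masks.glom, sample.masks.glom)

    def test_rotation_round_trip_dice(self):
        # 100-px disk rotated theta then -theta keeps Dice >= 0.95
        from podoseg.imaging import MaskPair, MultiChannelImage, SegSample
        mask = np.zeros((128, 128), dtype=np.uint8)
        yy, xx = np.mgrid[:128, :128]
        mask[(yy - 64)**2 + (xx - 64)**2 <= 50**2] = 1
        img = MultiChannelImage(np.repeat(mask[..., None], 3, axis=2)
                                .astype(np.float32))
        s = SegSample(img, MaskPair(mask, mask), "s", "g")
        cfg = TrainConfig(epochs=1)
        fwd = augment(s, cfg, transform=(False, False, 33.0, 0.0, 0.0))
        back = augment(fwd, cfg, transform=(False, False, -33.0, 0.0, 0.0))
        assert dice_pixel(mask, back.masks.glom) >= 0.95

    def test_same_seed_same_output(self, aug_sample):
        sample = aug_sample
        cfg = TrainConfig(epochs=1)
        a = augment(sample, cfg, seed=11)
        b = augment(sample, cfg, seed=11)
        assert np.array_equal(a.image.pixels, b.image.pixels)

    def test_masks_stay_binary(self, aug_sample):
        sample = aug_sample
        out = augment(sample, TrainConfig(epochs=1), seed=3)
        assert set(np.unique(out.masks.podo)) <= {0, 1}


class TestSplitBySubject:
    def _samples(self, n_subjects, per_subject):
        samples, _ = simulate_cohort(mini_cohort_spec(
            n_subjects_per_group=(n_subjects + 1) // 2,
            glomeruli_per_subject=(per_subject, per_subject)))
        subs = sorted({s.subject_id for s in samples})[:n_subjects]
        return [s for s in samples if s.subject_id in subs]

    def test_divisible_case(self):
        samples = self._samples(6, 3)
        tr, va, te = split_by_subject(samples, (0.6, 0.2, 0.2), seed=1)
        counts = sorted([len({s.subject_id for s in part})
                         for part in (tr, va, te)])
        assert sum(counts) == 6
        assert counts == [1, 1, 4] or counts == [1, 2, 3]

    def test_no_subject_spans_splits(self):
        samples = self._samples(6, 3)
        for seed in range(5):
            tr, va, te = split_by_subject(samples, seed=seed)
            sets = [{s.subject_id for s in part} for part in (tr, va, te)]
            assert not (sets[0] & sets[1] or sets[0] & sets[2]
                        or sets[1] & sets[2])

    def test_deterministic(self):
        samples = self._samples(6, 3)
        a = split_by_subject(samples, seed=3)
        b = split_by_subject(samples, seed=3)
        assert [[s.glomerulus_id for s in part] for part in a] == \
            [[s.glomerulus_id for s in part] for part in b]

    def test_realized_fractions_near_targets(self):
        samples, _ = simulate_cohort(mini_cohort_spec(
            n_subjects_per_group=10, glomeruli_per_subject=(3, 3)))
        tr, va, te = split_by_subject(samples, (0.6, 0.2, 0.2), seed=0)
        n = len(samples)
        assert abs(len(tr) / n - 0.6) <= 0.10
        assert abs(len(va) / n - 0.2) <= 0.10
        assert abs(len(te) / n - 0.2) <= 0.10

    def test_too_few_subjects(self):
        samples = self._samples(2, 3)
        with pytest.raises(ValueError):
            split_by_subject(samples)


class TestArchitecture:
    def test_output_shapes_match_input(self):
        model = build_dual_unet(UNetSpec(depth=3, base_filters=4), seed=0)
        x = np.zeros((1, 64, 64, 3), dtype=np.float32)
        out = model.forward(x)
        assert out["glom"].shape == (1, 64, 64, 1)
        assert out["podo"].shape == (1, 64, 64, 1)

    def test_filter_schedule(self):
        spec = UNetSpec(depth=3, base_filters=32)
        assert spec.bottom_filters == 256
        assert spec.filter_schedule == (32, 64, 128, 256, 128, 64, 32)

    def test_doubling_filters_quadruples_parameters(self):
        small = build_dual_unet(UNetSpec(depth=2, base_filters=8), seed=0)
        big = build_dual_unet(UNetSpec(depth=2, base_filters=16), seed=0)
        ratio = big.count_parameters() / small.count_parameters()
        assert 3.3 < ratio < 4.2

    def test_indivisible_size_rejected_by_forward(self):
        model = build_dual_unet(UNetSpec(depth=3, base_filters=4), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 100, 100, 3), dtype=np.float32))

    def test_predict_reflect_pads_odd_sizes(self):
        from podoseg.imaging import MultiChannelImage
        model = build_dual_unet(UNetSpec(depth=2, base_filters=4), seed=0)
        model.eval()
        img = MultiChannelImage(np.random.default_rng(0)
                                .random((70, 70, 3)).astype(np.float32))
        probs = predict(model, img)
        assert probs.glom_prob.shape == (70, 70)
        assert 0.0 <= probs.glom_prob.min() and probs.glom_prob.max() <= 1.0

    def test_predict_deterministic_in_eval(self):
        from podoseg.imaging import MultiChannelImage
        model = build_dual_unet(UNetSpec(depth=2, base_filters=4,
                                         dropout_bottom=True), seed=0)
        img = MultiChannelImage(np.random.default_rng(1)
                                .random((64, 64, 3)).astype(np.float32))
        a = predict(model, img)
        b = predict(model, img)
        assert np.array_equal(a.podo_prob, b.podo_prob)

    def test_checkpoint_roundtrip(self, tmp_path):
        from podoseg.imaging import MultiChannelImage
        model = build_dual_unet(UNetSpec(depth=2, base_filters=4), seed=3)
        path = tmp_path / "ckpt"
        save_checkpoint(model, path, dict(note="test"))
        loaded = load_checkpoint(path)
        img = MultiChannelImage(np.random.default_rng(2)
                                .random((64, 64, 3)).astype(np.float32))
        assert np.array_equal(predict(model, img).glom_prob,
                              predict(loaded, img).glom_prob)


class TestPostprocess:
    def _probs(self, podo_diams, glom_radius=40, shape=(128, 128)):
        glom = np.zeros(shape, dtype=np.float32)
        podo = np.zeros(shape, dtype=np.float32)
        yy, xx = np.mgrid[:shape[0], :shape[1]]
        glom[(yy - 64)**2 + (xx - 64)**2 <= glom_radius**2] = 0.9
        x = 30
        for d in podo_diams:
            podo[(yy - 64)**2 + (xx - x)**2 <= (d / 2)**2] = 0.9
            x += 25
        return ProbabilityPair(glom, podo)

    def test_all_zero_probs_empty_masks(self):
        probs = ProbabilityPair(np.zeros((64, 64)), np.zeros((64, 64)))
        masks, objs = postprocess(probs, 1.0)
        assert masks.glom.sum() == 0
        assert objs.n_objects == 0

    def test_largest_glomerulus_kept(self):
        glom = np.zeros((128, 128), dtype=np.float32)
        glom[10:40, 10:40] = 0.9            # 900 px
        glom[60:120, 60:120] = 0.9          # 3600 px
        probs = ProbabilityPair(glom, np.zeros_like(glom))
        masks, _ = postprocess(probs, 1.0, glom_min=(100.0, "um2_area"))
        assert masks.glom.sum() == 3600
        assert masks.glom[11, 11] == 0

    def test_small_nuclei_filtered(self):
        probs = self._probs([2.0, 5.0, 8.0])
        _, objs = postprocess(probs, 1.0, podo_min=(3.0, "um_diameter"))
        assert objs.n_objects == 2

    def test_area_unit_interpretation(self):
        probs = self._probs([6.0])
        _, by_diam = postprocess(probs, 1.0, podo_min=(3.0, "um_diameter"))
        _, by_area = postprocess(probs, 1.0, podo_min=(40.0, "um2_area"))
        assert by_diam.n_objects == 1
        assert by_area.n_objects == 0       # disk area ~ 28 um^2 < 40

    def test_invalid_threshold(self):
        probs = self._probs([5.0])
        with pytest.raises(ValueError):
            postprocess(probs, 1.0, thresholds=(0.0, 0.5))
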