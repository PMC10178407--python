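"""Augmentation, detail guidance, loss and training-loop contracts."""

import numpy as np
import pytest

from woundseg.nn import Tensor
from woundseg.segnet import build_network
from woundseg.synthetic import SCALED_CAMERA, generate_scenes
from woundseg.training import (
    AugmentationSpec,
    TrainConfig,
    augment,
    compute_loss,
    detail_ground_truth,
    expand_dataset,
    predict_mask,
    train,
)

from conftest import small_config

RNG = np.random.default_rng(99)

IDENTITY = AugmentationSpec(flip_angle_range=(0, 0), crop_fraction=1.0,
                            gaussian_noise_sigma=0.0, brightness_range=(1.0, 1.0))


def random_pair(h=40, w=60):
    img = (RNG.random((h, w, 3)) * 255).astype(np.uint8)
    mask = (RNG.random((h, w)) > 0.7).astype(np.uint8)
    return img, mask


class TestAugment:
    def test_identity_spec_returns_inputs_unchanged(self):
        img, mask = random_pair()
        out_img, out_mask = augment(img, mask, IDENTITY)
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_mask, mask)

    @pytest.mark.parametrize("angle", [90, 180, 270])
    def test_axis_aligned_rotation_moves_mask_exactly_with_image(self, angle):
        img, mask = random_pair(32, 32)
        spec = AugmentationSpec(flip_angle_range=(angle, angle), crop_fraction=1.0,
                                gaussian_noise_sigma=0.0, brightness_range=(1.0, 1.0))
        out_img, out_mask = augment(img, mask, spec)
        k = angle // 90
        assert np.array_equal(out_mask, np.rot90(mask, k))
        assert np.array_equal(out_img, np.rot90(img, k))

    def test_crop_to_one_third_side_length_exact(self):
        img = np.zeros((600, 600, 3), dtype=np.uint8)
        mask = np.zeros((600, 600), dtype=np.uint8)
        spec = AugmentationSpec(flip_angle_range=(0, 0), crop_fraction=1 / 3,
                                gaussian_noise_sigma=0.0, brightness_range=(1.0, 1.0))
        out_img, out_mask = augment(img, mask, spec)
        assert 200 in out_img.shape[:2]  # the randomly chosen dimension
        assert out_img.shape[:2] == out_mask.shape[:2]

    def test_same_seed_is_bit_identical(self):
        img, mask = random_pair()
        spec = AugmentationSpec(seed=42)
        a_img, a_mask = augment(img, mask, spec)
        b_img, b_mask = augment(img, mask, spec)
        assert np.array_equal(a_img, b_img)
        assert np.array_equal(a_mask, b_mask)

    def test_photometric_ops_never_touch_the_mask(self):
        img, mask = random_pair()
        spec = AugmentationSpec(flip_angle_range=(0, 0), crop_fraction=1.0,
                                gaussian_noise_sigma=0.2, brightness_range=(0.5, 1.5))
        _, out_mask = augment(img, mask, spec)
        assert np.array_equal(out_mask, mask)

    def test_arbitrary_angle_keeps_mask_binary(self):
        img, mask = random_pair(50, 50)
        spec = AugmentationSpec(flip_angle_range=(37.5, 37.5), crop_fraction=1.0,
                                gaussian_noise_sigma=0.0, brightness_range=(1.0, 1.0))
        _, out_mask = augment(img, mask, spec)
        assert set(np.unique(out_mask)) <= {0, 1}

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            augment(np.zeros((4, 4, 3), np.uint8), np.zeros((4, 5), np.uint8), IDENTITY)

    def test_expand_dataset_multiplies_size(self):
        pairs = [random_pair(24, 24) for _ in range(3)]
        out = expand_dataset(pairs, factor=4, spec=AugmentationSpec(), seed=0)
        assert len(out) == 12
        for i in range(3):  # originals kept verbatim
            assert np.array_equal(out[i][0], pairs[i][0])


class TestDetailGroundTruth:
    def test_constant_masks_have_no_edges(self):
        assert detail_ground_truth(np.zeros((16, 16), np.uint8)).sum() == 0
        assert detail_ground_truth(np.ones((16, 16), np.uint8)).sum() == 0

    def test_filled_square_yields_its_boundary_ring(self):
        mask = np.zeros((20, 20), np.uint8)
        mask[5:15, 5:15] = 1
        detail = detail_ground_truth(mask, scales=(1,))
        # oracle: pixels whose 8-neighbourhood crosses the region boundary
        ring = np.zeros_like(mask, dtype=bool)
        for y in range(20):
            for x in range(20):
                nb = mask[max(0, y - 1) : y + 2, max(0, x - 1) : x + 2]
                ring[y, x] = nb.min() != nb.max()
        assert np.array_equal(detail.astype(bool), ring)

    def test_rejects_non_binary_mask(self):
        with pytest.raises(ValueError, match="binary"):
            detail_ground_truth(np.full((8, 8), 3, np.uint8))


class TestComputeLoss:
    def _logits_for(self, mask, sharp=20.0):
        onehot = np.stack([1.0 - mask, mask], axis=1)
        return Tensor((onehot * 2 - 1) * sharp)

    def test_perfect_prediction_gives_near_zero_loss(self):
        mask = (RNG.random((2, 16, 16)) > 0.5).astype(np.float32)
        loss, _ = compute_loss(self._logits_for(mask), [], None, mask)
        assert loss.item() < 1e-4

    def test_loss_is_non_negative_on_random_inputs(self):
        mask = (RNG.random((1, 16, 16)) > 0.5).astype(np.float32)
        logits = Tensor(RNG.standard_normal((1, 2, 16, 16)))
        detail = Tensor(RNG.standard_normal((1, 1, 4, 4)))
        aux = [Tensor(RNG.standard_normal((1, 2, 4, 4)))]
        loss, comps = compute_loss(logits, aux, detail, mask)
        assert loss.item() >= 0.0
        assert set(comps) == {"seg", "aux", "detail"}

    def test_doubling_seg_weight_doubles_seg_component(self):
        mask = (RNG.random((1, 8, 8)) > 0.5).astype(np.float32)
        logits = Tensor(RNG.standard_normal((1, 2, 8, 8)))
        l1, c1 = compute_loss(logits, [], None, mask, weights=(1.0, 1.0, 1.0))
        l2, c2 = compute_loss(logits, [], None, mask, weights=(2.0, 1.0, 1.0))
        assert np.isclose(l2.item(), 2.0 * l1.item())
        assert np.isclose(c1["seg"].item(), c2["seg"].item())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_loss(Tensor(np.zeros((1, 2, 8, 8))), [], None, np.zeros((1, 9, 9)))


class TestTrainLoop:
    def test_zero_epochs_returns_initial_weights_and_empty_history(self):
        scenes = generate_scenes(2, seed=5, camera=SCALED_CAMERA)
        net = build_network(small_config(input_side=32))
        before = {k: v.copy() for k, v in net.state_dict().items()}
        result = train(scenes, net, TrainConfig(epochs=0, seed=0))
        assert result.history.empty
        after = net.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_empty_dataset_rejected(self):
        net = build_network(small_config(input_side=32))
        with pytest.raises(ValueError, match="empty"):
            train([], net, TrainConfig(epochs=1))

    def test_fixed_seed_reruns_produce_identical_histories(self):
        scenes = generate_scenes(2, seed=5, camera=SCALED_CAMERA,
                                 area_range_cm2=(15, 30), height_range_mm=(120, 200))
        histories = []
        for _ in range(2):
            net = build_network(small_config(input_side=32))
            res = train(scenes, net, TrainConfig(epochs=5, batch_size=2,
                                                 val_fraction=0.0, seed=17))
            histories.append(res.history)
        assert histories[0].equals(histories[1])


class TestPredictMask:
    def test_threshold_bounds_enforced(self):
        net = build_network(small_config(input_side=32))
        img = np.zeros((32, 32, 3), np.uint8)
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                predict_mask(net, img, threshold=bad)

    def test_raising_threshold_never_adds_wound_pixels(self):
        net = build_network(small_config(input_side=32))
        img = (RNG.random((40, 40, 3)) * 255).astype(np.uint8)
        masks = [predict_mask(net, img, threshold=t) for t in (0.3, 0.5, 0.7)]
        for lower, higher in zip(masks, masks[1:]):
            assert not np.any(higher & ~lower)
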