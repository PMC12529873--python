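"""DSNT head, Eq.-style loss, hand-written gradients, augmentation, resize."""

from __future__ import annotations

import math

import numpy as np
import pytest

from fedspine.geometry import LANDMARK_NAMES
from fedspine.model import (
    HourglassNet,
    ModelConfig,
    augment,
    dsnt_expect,
    dsnt_grid,
    js_divergence,
    load_checkpoint,
    loss,
    norm_from_px,
    px_from_norm,
    resize_with_aspect,
    rotate_sample,
    save_checkpoint,
    target_heatmap,
)
from fedspine.nn import Adam
from fedspine.synthetic import generate_cohort

from conftest import EQUAL_PROFILES, landmarks_from_angles

MICRO = ModelConfig(
    input_size=16, base_channels=2, heatmap_stride=4, n_landmarks=2, dtype="float64"
)


class TestDSNT:
    def test_grid_formula(self):
        assert dsnt_grid(3) == pytest.approx([-2 / 3, 0.0, 2 / 3])
        n = 10
        assert dsnt_grid(n)[0] == pytest.approx((2 * 1 - (n + 1)) / n)

    def test_one_hot_center_of_odd_grid_maps_to_origin(self):
        hm = np.zeros((1, 1, 5, 5))
        hm[0, 0, 2, 2] = 1.0
        assert dsnt_expect(hm) == pytest.approx(np.zeros((1, 1, 2)))

    def test_one_hot_first_pixel_of_3_grid(self):
        hm = np.zeros((1, 1, 3, 3))
        hm[0, 0, 0, 0] = 1.0
        assert dsnt_expect(hm)[0, 0] == pytest.approx([-2 / 3, -2 / 3])

    def test_uniform_heatmap_maps_to_origin(self):
        hm = np.full((2, 3, 8, 8), 1 / 64.0)
        assert np.abs(dsnt_expect(hm)).max() < 1e-12

    def test_expectation_matches_bruteforce_sum(self):
        rng = np.random.default_rng(0)
        hm = rng.uniform(size=(4, 6, 12, 12))
        hm /= hm.sum(axis=(-2, -1), keepdims=True)
        got = dsnt_expect(hm)
        gx, gy = dsnt_grid(12), dsnt_grid(12)
        for n in range(4):
            for l in range(6):
                bx = sum(
                    hm[n, l, i, j] * gx[j] for i in range(12) for j in range(12)
                )
                by = sum(
                    hm[n, l, i, j] * gy[i] for i in range(12) for j in range(12)
                )
                assert got[n, l] == pytest.approx([bx, by], abs=1e-10)

    def test_px_norm_round_trip(self):
        px = np.array([0.0, 31.5, 63.0])
        assert px_from_norm(norm_from_px(px, 64), 64) == pytest.approx(px)


class TestTargetHeatmap:
    def test_sums_to_one(self):
        cfg = ModelConfig(input_size=64, n_landmarks=5)
        rng = np.random.default_rng(1)
        gt = rng.uniform(-0.9, 0.9, size=(3, 5, 2))
        hm = target_heatmap(gt, cfg)
        assert hm.sum(axis=(-2, -1)) == pytest.approx(np.ones((3, 5)), abs=1e-6)

    def test_argmax_is_nearest_grid_pixel(self):
        cfg = ModelConfig(input_size=64, n_landmarks=1, sigma_hm=1.0)
        n = cfg.heatmap_size
        gt = np.array([[[0.3, -0.5]]])
        hm = target_heatmap(gt, cfg)[0, 0]
        iy, ix = np.unravel_index(hm.argmax(), hm.shape)
        cx = (gt[0, 0, 0] * n + n - 1) / 2
        cy = (gt[0, 0, 1] * n + n - 1) / 2
        # ties at half-integer centers may go to either neighbour
        assert abs(ix - cx) <= 0.5 and abs(iy - cy) <= 0.5

    def test_small_sigma_expectation_within_half_heatmap_pixel(self):
        cfg = ModelConfig(input_size=64, n_landmarks=1, sigma_hm=0.3)
        rng = np.random.default_rng(2)
        gt = rng.uniform(-0.8, 0.8, size=(5, 1, 2))
        coords = dsnt_expect(target_heatmap(gt, cfg).astype(np.float64))
        # half a heatmap pixel in normalized units is 1/heatmap_size
        assert np.abs(coords - gt).max() <= 1.0 / cfg.heatmap_size


class TestLoss:
    def _pair(self):
        cfg = MICRO
        gt = np.array([[[0.1, -0.2], [0.3, 0.4]]])
        return gt, target_heatmap(gt, cfg)

    def test_zero_at_perfect_prediction(self):
        gt, hm = self._pair()
        assert loss(gt, gt, hm, hm) == pytest.approx(0.0, abs=1e-12)

    def test_euclidean_term_is_three_four_five(self):
        gt, hm = self._pair()
        pred = gt + np.array([0.6, 0.8])
        assert loss(pred, gt, hm, hm) == pytest.approx(1.0, abs=1e-12)

    def test_js_term_matches_direct_summation(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=(5, 5))
        p /= p.sum()
        q = rng.uniform(size=(5, 5))
        q /= q.sum()
        m = 0.5 * (p + q)
        direct = 0.5 * sum(
            p[i, j] * math.log(p[i, j] / m[i, j])
            + q[i, j] * math.log(q[i, j] / m[i, j])
            for i in range(5)
            for j in range(5)
        )
        assert js_divergence(p, q) == pytest.approx(direct, abs=1e-10)

    def test_unnormalized_heatmaps_rejected(self):
        gt, hm = self._pair()
        with pytest.raises(ValueError, match="not normalized"):
            loss(gt, gt, 2 * hm, hm)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        net = HourglassNet(MICRO)
        params = net.init_params(0)
        assert params.total_count <= 1000
        rng = np.random.default_rng(1)
        imgs = rng.uniform(0, 1, (2, 16, 16))
        gt = rng.uniform(-0.8, 0.8, (2, 2, 2))
        base, grads, _ = net.loss_and_grads(params, imgs, gt)
        eps = 1e-6
        for name in params.keys():
            flat = params[name].reshape(-1)
            idxs = rng.choice(flat.size, size=min(6, flat.size), replace=False)
            for i in idxs:
                old = flat[i]
                flat[i] = old + eps
                up, _, _ = net.loss_and_grads(params, imgs, gt)
                flat[i] = old - eps
                dn, _, _ = net.loss_and_grads(params, imgs, gt)
                flat[i] = old
                fd = (up - dn) / (2 * eps)
                an = grads[name].reshape(-1)[i]
                assert an == pytest.approx(fd, rel=1e-4, abs=1e-7), name

    def test_overfits_eight_samples_below_two_pixels(self):
        """Desk preset memorizes 8 images within 200 steps (learning sanity)."""
        samples = generate_cohort(
            EQUAL_PROFILES, n_patients=4, rng_seed=5, canvas=(64, 64), spacing_mm=2.0
        )[:8]
        cfg = ModelConfig(input_size=64, n_stacks=1, base_channels=16)
        net = HourglassNet(cfg)
        params = net.init_params(0)
        imgs = np.stack([s.image for s in samples])
        gt_px = np.array(
            [[s.landmarks.points[n] for n in LANDMARK_NAMES] for s in samples]
        )
        gt = norm_from_px(gt_px, 64)
        hm_gt = target_heatmap(gt, cfg)
        opt = Adam(params)
        for _ in range(200):
            _, grads, _ = net.loss_and_grads(params, imgs, gt, hm_gt)
            opt.step(params, grads, 2e-3)
        pred = net.predict_px(params, imgs)
        err = np.linalg.norm(pred - gt_px, axis=-1).mean()
        assert err < 2.0


class TestForwardContract:
    def test_heatmaps_normalized_and_coords_finite(self, tiny_model_cfg):
        net = HourglassNet(tiny_model_cfg)
        params = net.init_params(3)
        imgs = np.random.default_rng(0).uniform(0, 1, (3, 32, 32))
        hms, coords = net.forward(params, imgs)
        assert len(hms) == tiny_model_cfg.n_stacks
        assert hms[-1].shape == (3, 29, 8, 8)
        assert hms[-1].sum(axis=(-2, -1)) == pytest.approx(
            np.ones((3, 29)), abs=1e-5
        )
        assert coords.shape == (3, 29, 2)
        assert np.isfinite(coords).all()

    def test_shape_mismatch_raises(self, tiny_model_cfg):
        net = HourglassNet(tiny_model_cfg)
        params = net.init_params(3)
        with pytest.raises(ValueError, match="expected 32x32"):
            net.forward(params, np.zeros((1, 16, 16)))

    def test_multi_stack_output_count(self):
        cfg = ModelConfig(input_size=32, n_stacks=2, base_channels=4)
        net = HourglassNet(cfg)
        hms, _ = net.forward(net.init_params(0), np.zeros((1, 32, 32)))
        assert len(hms) == 2


class TestAugment:
    def _sample(self):
        lm = landmarks_from_angles(seed=5, canvas=(64, 64), spacing=2.0)
        rng = np.random.default_rng(0)
        return rng.uniform(0, 1, (64, 64)), lm

    def test_zero_rotation_leaves_landmarks(self):
        img, lm = self._sample()
        _, lm2 = augment(img, lm, rng_seed=4, max_rotation_deg=0.0)
        for k, v in lm.points.items():
            assert lm2.points[k] == pytest.approx(v, abs=1e-12)

    def test_deterministic_per_seed(self):
        img, lm = self._sample()
        a_img, a_lm = augment(img, lm, rng_seed=11)
        b_img, b_lm = augment(img, lm, rng_seed=11)
        assert np.array_equal(a_img, b_img)
        assert a_lm.points == b_lm.points

    def test_rotation_matches_matrix_oracle(self):
        img, lm = self._sample()
        theta = 10.0
        _, rot_lm = rotate_sample(img, lm, theta)
        t = math.radians(theta)
        c = np.array([31.5, 31.5])
        rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
        for k, v in lm.points.items():
            want = c + rot @ (np.asarray(v) - c)
            assert rot_lm.points[k] == pytest.approx(tuple(want), abs=1e-9)

    def test_rotated_image_follows_landmarks(self):
        # a bright dot at a landmark stays at the transformed landmark
        img = np.zeros((64, 64))
        lm = landmarks_from_angles(seed=5, canvas=(64, 64), spacing=2.0)
        x, y = lm.points["S1_midpoint"]
        img[int(round(y)), int(round(x))] = 1.0
        rimg, rlm = rotate_sample(img, lm, 8.0)
        ry, rx = np.unravel_index(rimg.argmax(), rimg.shape)
        nx, ny = rlm.points["S1_midpoint"]
        assert math.hypot(rx - nx, ry - ny) < 1.5


class TestResizeWithAspect:
    def test_square_input_is_pure_scaling(self):
        img = np.random.default_rng(0).uniform(0, 1, (64, 64))
        lm = landmarks_from_angles(seed=1, canvas=(64, 64), spacing=2.0)
        out, lm2, tf = resize_with_aspect(img, lm, 32)
        assert out.shape == (32, 32)
        assert tf.pad_x == 0 and tf.pad_y == 0
        assert tf.scale == pytest.approx(0.5)

    def test_rectangular_padding_arithmetic(self):
        img = np.random.default_rng(0).uniform(0, 1, (100, 200))
        out, _, tf = resize_with_aspect(img, None, 64)
        assert out.shape == (64, 64)
        assert tf.scale == pytest.approx(64 / 200)
        assert tf.pad_y == (64 - 32) // 2 and tf.pad_x == 0

    def test_round_trip_recovers_landmarks(self):
        img = np.random.default_rng(0).uniform(0, 1, (100, 200))
        pts = np.array([[10.0, 20.0], [150.0, 90.0], [73.25, 41.5]])
        _, _, tf = resize_with_aspect(img, None, 64)
        assert tf.invert(tf.apply(pts)) == pytest.approx(pts, abs=1e-6)


class TestCheckpoint:
    def test_bit_stable_reload(self, tmp_path, tiny_model_cfg):
        net = HourglassNet(tiny_model_cfg)
        params = net.init_params(9)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, params, tiny_model_cfg, {"best_val_metric": 1.25})
        back, cfg, meta = load_checkpoint(path)
        assert cfg == tiny_model_cfg
        assert meta == {"best_val_metric": 1.25}
        assert back.equal(params)
        assert list(back.keys()) == list(params.keys())
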