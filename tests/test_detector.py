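"""Detector losses, matching, forward pass, augmentation and training."""

import math

import numpy as np
import pytest

from jointscan.boxes import FeatureMapSpec, GridConfig, iou_matrix, make_default_boxes
from jointscan.detector import (
    MultiboxDetector,
    TrainConfig,
    augment,
    confidence_loss,
    localization_loss,
    match_defaults,
    smooth_l1,
    softmax,
    total_loss,
    train_detector,
    window_loss_and_grads,
)

TOY_GRID = GridConfig(window=16, feature_maps=(
    FeatureMapSpec(size=2, scale=0.4, aspect_ratios=(1.0,)),))


def toy_grid():
    return make_default_boxes(TOY_GRID)


class TestSmoothL1:
    @pytest.mark.parametrize("x,expected", [
        (0.0, 0.0),
        (0.5, 0.125),
        (-0.5, 0.125),
        (2.0, 1.5),
        (-3.0, 2.5),
        (1.0, 0.5),  # continuous at the knee
    ])
    def test_values(self, x, expected):
        assert smooth_l1(x) == pytest.approx(expected)

    def test_continuity_at_knee(self):
        eps = 1e-8
        assert smooth_l1(1 - eps) == pytest.approx(smooth_l1(1 + eps), abs=1e-6)


class TestMatching:
    def test_gt_equal_to_default_is_matched(self):
        grid = toy_grid()
        gt = grid.boxes[[1]]
        a = match_defaults(gt, grid, 0.5)
        assert a.n_matched >= 1
        assert a.gt_index[1] == 0

    def test_empty_gt_all_negative(self):
        a = match_defaults(np.zeros((0, 4)), toy_grid(), 0.5)
        assert a.n_matched == 0
        assert np.all(a.neg)

    def test_every_gt_gets_a_default(self, rng):
        grid = toy_grid()
        for _ in range(20):
            gts = np.column_stack([
                rng.uniform(2, 14, 2), rng.uniform(2, 14, 2),
                rng.uniform(2, 8, 2), rng.uniform(2, 8, 2)])
            a = match_defaults(gts, grid, 0.5)
            matched_gts = set(a.gt_index[a.pos])
            assert matched_gts == {0, 1}

    def test_matches_exhaustive_argmax_oracle(self):
        """Greedy forced matching equals brute-force max-IoU pairing on a toy grid."""
        grid = toy_grid()
        gts = np.array([[4.0, 4.0, 6.0, 6.0], [12.0, 12.0, 5.0, 5.0]])
        a = match_defaults(gts, grid, match_iou=0.99)  # isolate the forced matches
        M = iou_matrix(grid.boxes, gts)
        # brute force greedy over all pairs
        expect = {}
        work = M.copy()
        for _ in range(2):
            i, j = np.unravel_index(np.argmax(work), work.shape)
            expect[i] = j
            work[i, :] = -1
            work[:, j] = -1
        got = {i: a.gt_index[i] for i in np.flatnonzero(a.pos)}
        assert got == expect

    def test_one_gt_per_matched_default(self, rng):
        grid = toy_grid()
        gts = np.column_stack([
            rng.uniform(2, 14, 3), rng.uniform(2, 14, 3),
            rng.uniform(2, 8, 3), rng.uniform(2, 8, 3)])
        a = match_defaults(gts, grid, 0.3)
        # gt_index is single-valued per default: each default links to one gt
        assert a.gt_index[a.pos].min() >= 0


class TestLosses:
    def _assign(self, n_pos=1, labels=None):
        grid = toy_grid()
        gt = grid.boxes[:n_pos].copy()
        lab = np.zeros(n_pos, dtype=bool) if labels is None else np.asarray(labels)
        return match_defaults(gt, grid, 0.99, lab), grid

    def test_perfect_offsets_zero_loss(self):
        a, grid = self._assign(1)
        from jointscan.boxes import encode_array
        offsets = np.zeros((len(grid), 4))
        pos = np.flatnonzero(a.pos)
        offsets[pos] = encode_array(a.gt_boxes[a.gt_index[pos]], grid.boxes[pos])
        assert localization_loss(a, offsets, offsets) == 0.0

    def test_single_coordinate_off_by_half(self):
        a, grid = self._assign(1)
        targets = np.zeros((len(grid), 4))
        preds = targets.copy()
        pos = np.flatnonzero(a.pos)[0]
        preds[pos, 0] = 0.5
        assert localization_loss(a, preds, targets) == pytest.approx(0.125)

    def test_empty_pos_zero(self):
        grid = toy_grid()
        a = match_defaults(np.zeros((0, 4)), grid, 0.5)
        assert localization_loss(a, np.zeros((len(grid), 4)), np.zeros((len(grid), 4))) == 0.0

    def test_shape_mismatch_rejected(self):
        a, grid = self._assign(1)
        with pytest.raises(ValueError):
            localization_loss(a, np.zeros((len(grid), 4)), np.zeros((2, 4)))

    def test_uniform_logits_single_pos_no_neg(self):
        """One matched box with uniform logits contributes -log(1/3) = ln 3."""
        grid_cfg = GridConfig(window=16, feature_maps=(
            FeatureMapSpec(size=1, scale=0.5, aspect_ratios=(1.0,)),))
        grid = make_default_boxes(grid_cfg)
        a = match_defaults(grid.boxes[[0]], grid, 0.99)
        assert a.n_matched == 1 and len(grid) == 1
        loss = confidence_loss(a, np.zeros((1, 3)))
        assert loss == pytest.approx(math.log(3))

    def test_hard_negative_ratio_counts(self):
        """2 positives + 6 negative candidates at 3:1 -> exactly 6 negatives counted."""
        grid_cfg = GridConfig(window=16, feature_maps=(
            FeatureMapSpec(size=2, scale=0.4, aspect_ratios=(1.0, 2.0)),))
        grid = make_default_boxes(grid_cfg)  # 8 boxes
        a = match_defaults(grid.boxes[[0, 3]], grid, 0.99)
        assert a.n_matched == 2
        logits = np.zeros((8, 3))
        # uniform logits: every counted box contributes ln 3
        loss = confidence_loss(a, logits, neg_pos_ratio=3, neg_iou_max=1.0)
        assert loss == pytest.approx((2 + 6) * math.log(3))

    def test_near_matches_excluded_from_negative_pool(self):
        """Defaults overlapping a gt above the ignore threshold are not mined."""
        grid_cfg = GridConfig(window=16, feature_maps=(
            FeatureMapSpec(size=2, scale=0.4, aspect_ratios=(1.0, 2.0)),))
        grid = make_default_boxes(grid_cfg)
        a = match_defaults(grid.boxes[[0]], grid, 0.99)
        assert a.n_matched == 1
        pool = a.neg_pool(0.3)
        # the unmatched same-cell aspect-ratio variant overlaps the gt strongly
        assert not pool[1]
        # counted boxes: 1 pos + eligible negatives only
        loss = confidence_loss(a, np.zeros((8, 3)), neg_pos_ratio=3, neg_iou_max=0.3)
        n_counted = 1 + min(3, int(pool.sum()))
        assert loss == pytest.approx(n_counted * math.log(3))

    def test_confident_correct_classes_drive_loss_to_zero(self):
        a, grid = self._assign(1, labels=[True])
        logits = np.zeros((len(grid), 3))
        logits[:, 0] = 50.0  # confident background everywhere
        pos = np.flatnonzero(a.pos)[0]
        logits[pos] = [0.0, 50.0, 0.0]  # confident present on the matched box
        assert confidence_loss(a, logits) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("conf,loc,n,expected", [
        (2.0, 1.0, 2, 1.5),
        (0.0, 0.0, 5, 0.0),
        (3.0, 3.0, 0, 0.0),
    ])
    def test_total_loss(self, conf, loc, n, expected):
        assert total_loss(conf, loc, n) == pytest.approx(expected)

    def test_loss_invariant_to_gt_order(self, rng):
        grid = toy_grid()
        gts = np.array([[4.0, 4.0, 6.0, 6.0], [12.0, 12.0, 5.0, 5.0]])
        labels = np.array([True, False])
        logits = rng.normal(size=(len(grid), 3))
        offsets = rng.normal(size=(len(grid), 4))
        losses = []
        for perm in ([0, 1], [1, 0]):
            a = match_defaults(gts[perm], grid, 0.5, labels[perm])
            c, l, _, _, n = window_loss_and_grads(a, logits, offsets, grid)
            losses.append(total_loss(c, l, n))
        assert losses[0] == pytest.approx(losses[1])


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        """Network+loss gradients agree with central differences to 1e-4."""
        gc = GridConfig(window=16, feature_maps=(
            FeatureMapSpec(size=2, scale=0.4, aspect_ratios=(1.0, 2.0)),))
        det = MultiboxDetector(grid_config=gc, channels=(4, 4, 4), taps=(2,),
                               seed=3, dtype=np.float64)
        rng = np.random.default_rng(0)
        x = rng.random((1, 3, 16, 16))
        gts = np.array([[8.0, 8.0, 6.0, 6.0]])
        assign = match_defaults(gts, det.grid, 0.5, np.array([True]))

        def loss_value():
            logits, offs = det.forward(x)
            c, l, dl, do, n = window_loss_and_grads(assign, logits[0], offs[0], det.grid)
            return total_loss(c, l, n), dl, do, n

        _, dl, do, n = loss_value()
        det.forward(x)
        det.backward(dl[None] / n, do[None] / n)
        params = det.parameters()
        eps = 1e-6
        for (p, g) in params:
            flat, gflat = p.ravel(), g.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp, *_ = loss_value()
                flat[i] = old - eps
                lm, *_ = loss_value()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - gflat[i]) < 1e-4 * max(1.0, abs(num))


class TestForward:
    def test_output_length_matches_grid(self):
        det = MultiboxDetector(seed=0)
        x = np.zeros((3, 64, 64))
        logits, offsets = det.forward(x)
        assert logits.shape == (len(det.grid), 3)
        assert offsets.shape == (len(det.grid), 4)

    def test_wrong_window_shape_rejected(self):
        det = MultiboxDetector(seed=0)
        with pytest.raises(ValueError):
            det.forward(np.zeros((3, 32, 32)))

    def test_deterministic_given_seed(self, rng):
        x = rng.random((3, 64, 64))
        out1 = MultiboxDetector(seed=5).forward(x)
        out2 = MultiboxDetector(seed=5).forward(x)
        np.testing.assert_array_equal(out1[0], out2[0])
        np.testing.assert_array_equal(out1[1], out2[1])

    def test_softmax_normalised(self, rng):
        p = softmax(rng.normal(size=(10, 3)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        det = MultiboxDetector(seed=9, task="subluxation")
        det.loss_history = [1.0, 0.5]
        det.epochs_trained = 2
        path = tmp_path / "det.npz"
        det.save(path)
        back = MultiboxDetector.load(path)
        assert back.task == "subluxation"
        assert back.epochs_trained == 2
        x = rng.random((3, 64, 64))
        np.testing.assert_array_equal(det.forward(x)[0], back.forward(x)[0])


class TestAugment:
    def _boxes(self):
        return np.array([[20.0, 30.0, 10.0, 8.0]])

    def test_identity_when_no_transform_fires(self, rng):
        w = rng.random((64, 64))
        out, boxes, _ = augment(w, self._boxes(), np.array([True]), rng, prob=0.0)
        np.testing.assert_array_equal(out, w)
        np.testing.assert_array_equal(boxes, self._boxes())

    def test_horizontal_flip_maps_cx(self):
        class FlipOnly:
            calls = 0

            def random(self):
                FlipOnly.calls += 1
                return 0.9 if FlipOnly.calls < 4 else 0.1  # only 4th draw fires

            def uniform(self, a, b):
                return (a + b) / 2

        w = np.zeros((64, 64))
        w[10, 5] = 1.0
        out, boxes, _ = augment(w, self._boxes(), np.array([False]), FlipOnly(), prob=0.5)
        assert boxes[0, 0] == pytest.approx(64 - 20)
        assert out[10, 64 - 1 - 5] == 1.0

    def test_rotation_maps_center_per_quarter_turn(self):
        class RotOnly:
            calls = 0

            def random(self):
                RotOnly.calls += 1
                return 0.1 if RotOnly.calls == 3 else 0.9

            def integers(self, a, b):
                return 1

        H = 64
        w = np.zeros((H, H))
        out, boxes, _ = augment(w, self._boxes(), np.array([False]), RotOnly(), prob=0.5)
        # (cx, cy) -> (H - cy, cx), sides swap
        assert boxes[0].tolist() == pytest.approx([H - 30, 20, 8, 10])


class TestTraining:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_detector([], "ankylosis", TrainConfig(epochs=1))

    def test_loss_decreases_and_is_reproducible(self, phantom_dataset):
        cfg = TrainConfig(epochs=2)
        subset = phantom_dataset[:4]
        det1 = train_detector(subset, "ankylosis", cfg, seed=21)
        assert det1.loss_history[-1] < det1.loss_history[0]
        det2 = train_detector(subset, "ankylosis", cfg, seed=21)
        np.testing.assert_array_equal(det1.parameters()[0][0], det2.parameters()[0][0])

    def test_crops_per_epoch_arithmetic(self):
        # an epoch draws one crop per annotated joint per image
        n_images, joints_per_image = 210, 20
        assert n_images * joints_per_image == 4200
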