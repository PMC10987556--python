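"""Ground-truth matching, confusion counts, metric and fold arithmetic."""

import itertools
import math

import numpy as np
import pytest

from jointscan.evaluation import (
    ConfusionCounts,
    GTAssignment,
    average_folds,
    confusion,
    detection_rate,
    match_to_ground_truth,
    metrics,
    round_half_up,
    stratified_five_fold,
)

# Published five-fold confusion counts for the two finding tasks.
SUBLUX_FOLDS = [  # TP, FP, TN, FN
    (6, 2, 887, 5),
    (9, 2, 889, 1),
    (17, 3, 880, 0),
    (8, 5, 882, 3),
    (8, 0, 889, 3),
]
ANKYLOSIS_FOLDS = [
    (24, 1, 965, 8),
    (24, 0, 967, 8),
    (28, 1, 969, 3),
    (27, 1, 969, 4),
    (24, 0, 969, 7),
]


def counts(tp, fp, tn, fn):
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


class TestMatching:
    def test_perfect_predictions_all_detected(self):
        gts = np.array([[10.0, 10, 8, 8], [40, 40, 8, 8], [70, 10, 8, 8]])
        a = match_to_ground_truth(gts.copy(), gts)
        assert a.detected.all()
        assert a.iou == pytest.approx([1.0, 1.0, 1.0])

    def test_below_threshold_not_detected(self):
        # a shift giving IoU 1/3 (< 0.45) on every joint
        gts = np.array([[10.0, 10, 2, 2], [40, 40, 2, 2]])
        preds = gts + np.array([1.0, 0, 0, 0])
        a = match_to_ground_truth(preds, gts)
        assert a.iou == pytest.approx([1 / 3, 1 / 3])
        assert not a.detected.any()

    def test_matches_bruteforce_assignment_oracle(self, rng):
        """Greedy matching equals the exhaustive greedy oracle over permutations."""
        for _ in range(100):
            G = int(rng.integers(1, 5))
            P = int(rng.integers(1, 5))
            gts = np.column_stack([rng.uniform(0, 60, G), rng.uniform(0, 60, G),
                                   rng.uniform(5, 25, G), rng.uniform(5, 25, G)])
            preds = np.column_stack([rng.uniform(0, 60, P), rng.uniform(0, 60, P),
                                     rng.uniform(5, 25, P), rng.uniform(5, 25, P)])
            a = match_to_ground_truth(preds, gts)
            # oracle: repeatedly take the globally best remaining (pred, gt) pair
            from jointscan.boxes import iou_matrix

            M = iou_matrix(preds, gts)
            work = M.copy()
            expect = np.full(G, -1)
            for _ in range(min(P, G)):
                p, g = np.unravel_index(np.argmax(work), work.shape)
                if work[p, g] <= 0:
                    break
                expect[g] = p
                work[p, :] = -1
                work[:, g] = -1
            np.testing.assert_array_equal(a.pred_index, expect)

    def test_one_to_one(self):
        # one prediction cannot detect two joints
        gts = np.array([[10.0, 10, 8, 8], [13, 10, 8, 8]])
        preds = np.array([[11.0, 10, 8, 8]])
        a = match_to_ground_truth(preds, gts)
        assert (a.pred_index >= 0).sum() == 1


class TestDetectionRate:
    def test_all_detected(self):
        assert detection_rate(900, 900) == 100.0

    def test_table_style_rounding(self):
        assert round(detection_rate(899, 900), 2) == 99.89

    def test_none_detected(self):
        assert detection_rate(0, 900) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            detection_rate(0, 0)


class TestConfusion:
    def _assign(self, n, detected=None):
        det = np.ones(n, dtype=bool) if detected is None else np.asarray(detected)
        return GTAssignment(pred_index=np.arange(n), iou=np.where(det, 0.9, 0.0),
                            detected=det, iou_success=0.45)

    def test_all_correct_positives(self):
        a = self._assign(4)
        c = confusion(a, [True] * 4, [True] * 4)
        assert (c.tp, c.fp, c.tn, c.fn) == (4, 0, 0, 0)

    def test_hand_enumerated_fold(self):
        """10 joints with 2 label flips match hand enumeration."""
        gt = [True, True, True, False, False, False, False, False, False, False]
        pred = [True, True, False, True, False, False, False, False, False, False]
        c = confusion(self._assign(10), pred, gt)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 6, 1)

    def test_all_negative_world(self):
        c = confusion(self._assign(5), [False] * 5, [False] * 5)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 5)

    def test_undetected_joints_excluded(self):
        # detection failures never enter the classification table
        det = [True, False, True]
        c = confusion(self._assign(3, det), [True, True, False], [True, True, True])
        assert (c.tp, c.fn) == (1, 1)
        assert c.total == 2

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestMetrics:
    def test_published_subluxation_fold5(self):
        m = metrics(counts(8, 0, 889, 3))
        assert m.precision == pytest.approx(1.0)
        assert m.recall == pytest.approx(8 / 11)

    def test_published_ankylosis_fold1(self):
        m = metrics(counts(24, 1, 965, 8))
        assert m.precision == pytest.approx(24 / 25)

    def test_degenerate_single_positive_single_negative(self):
        m = metrics(counts(1, 0, 1, 0))
        for name in ("accuracy", "precision", "recall", "specificity", "f_value"):
            assert getattr(m, name) == pytest.approx(1.0)

    def test_undefined_ratios_are_nan(self):
        m = metrics(counts(0, 0, 5, 0))
        assert math.isnan(m.precision) and math.isnan(m.recall)
        assert m.accuracy == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            metrics(counts(0, 0, 0, 0))

    def test_f_value_consistency(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 50, 4))
            m = metrics(counts(tp, fp, tn, fn))
            assert m.f_value == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall))

    def test_matches_bruteforce_enumeration(self, rng):
        """metrics(confusion(...)) equals a one-pass enumeration oracle."""
        n = 40
        det = rng.random(n) < 0.9
        gt = rng.random(n) < 0.3
        pred = rng.random(n) < 0.3
        a = GTAssignment(pred_index=np.arange(n), iou=np.where(det, 0.9, 0.2),
                         detected=det, iou_success=0.45)
        m = metrics(confusion(a, pred, gt))
        # oracle
        tp = fp = tn = fn = 0
        for i in range(n):
            if not det[i]:
                continue
            if gt[i] and pred[i]:
                tp += 1
            elif gt[i]:
                fn += 1
            elif pred[i]:
                fp += 1
            else:
                tn += 1
        assert m.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))
        if tp + fp:
            assert m.precision == pytest.approx(tp / (tp + fp))


class TestFoldAveraging:
    def test_published_subluxation_averages(self):
        """Per-fold counts reproduce the published means 0.81 / 0.78 / 0.78."""
        folds = [metrics(counts(*f)) for f in SUBLUX_FOLDS]
        avg = average_folds(folds).rounded()
        assert avg.precision == 0.81
        assert avg.recall == 0.78
        assert avg.f_value == 0.78
        assert avg.accuracy == 0.99
        assert avg.specificity == 1.0  # 0.997 rounds up at two decimals

    def test_published_ankylosis_averages(self):
        """Per-fold counts reproduce the published means 0.98 / 0.81 / 0.88."""
        folds = [metrics(counts(*f)) for f in ANKYLOSIS_FOLDS]
        avg = average_folds(folds).rounded()
        assert avg.precision == 0.98
        assert avg.recall == 0.81
        assert avg.f_value == 0.88
        assert avg.accuracy == 0.99

    def test_positives_totals(self):
        assert sum(f[0] + f[3] for f in SUBLUX_FOLDS) == 60
        assert sum(f[0] + f[3] for f in ANKYLOSIS_FOLDS) == 157

    def test_identical_folds_mean_equals_any(self):
        m = metrics(counts(5, 1, 90, 2))
        avg = average_folds([m, m, m])
        assert avg.precision == pytest.approx(m.precision)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_folds([])

    def test_nan_folds_excluded_from_mean(self):
        m1 = metrics(counts(0, 0, 10, 0))  # precision undefined
        m2 = metrics(counts(5, 0, 10, 0))
        avg = average_folds([m1, m2])
        assert avg.precision == pytest.approx(1.0)

    def test_half_up_rounding(self):
        assert round_half_up(0.885) == 0.89
        assert round_half_up(0.884999) == 0.88
        assert round_half_up(0.975) == 0.98


class TestStratifiedSplit:
    def test_partition_and_sizes(self, phantom_dataset):
        split = stratified_five_fold(phantom_dataset, seed=0)
        all_test = sorted(itertools.chain.from_iterable(split.test_ids))
        assert all_test == list(range(len(phantom_dataset)))
        for tr, te in zip(split.train_ids, split.test_ids):
            assert sorted(tr + te) == list(range(len(phantom_dataset)))

    def test_deterministic(self, phantom_dataset):
        s1 = stratified_five_fold(phantom_dataset, seed=7)
        s2 = stratified_five_fold(phantom_dataset, seed=7)
        assert s1.test_ids == s2.test_ids

    def test_patients_not_split_across_folds(self, phantom_dataset):
        split = stratified_five_fold(phantom_dataset, seed=0)
        for te in split.test_ids:
            pats = {phantom_dataset[i].patient_id for i in te}
            for tr in [t for t in split.train_ids][split.test_ids.index(te):][:1]:
                pass
            # a patient in this test fold must not appear in its train fold
            k = split.test_ids.index(te)
            train_pats = {phantom_dataset[i].patient_id for i in split.train_ids[k]}
            assert not (pats & train_pats)

    def test_positive_images_spread(self):
        """Toy: 10 images, 2 positive patients -> positives land in different folds."""
        from jointscan.phantoms import PhantomParams, generate_dataset

        params = PhantomParams(image_w=256, image_h=224, ankylosis_prevalence=0.0)
        data = generate_dataset(10, params, seed=1)
        # force exactly two positive patients
        for img in data[:4]:
            img.joints[0] = img.joints[0].__class__(
                **{**img.joints[0].__dict__, "has_ankylosis": True})
        split = stratified_five_fold(data, seed=3)
        pos_folds = [
            k for k, te in enumerate(split.test_ids)
            if any(any(j.has_ankylosis for j in data[i].joints) for i in te)
        ]
        assert len(pos_folds) == 2  # the two positive patients sit in two folds

    def test_test_size_trimming(self, phantom_dataset):
        split = stratified_five_fold(phantom_dataset, seed=0, test_size=2)
        # 10 images over 5 folds -> each test fold trimmed to one patient (2 films)
        for te, tr in zip(split.test_ids, split.train_ids):
            assert len(te) == 2
            assert len(tr) == 8

    def test_too_few_images_rejected(self, phantom_dataset):
        with pytest.raises(ValueError):
            stratified_five_fold(phantom_dataset[:3], seed=0)
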