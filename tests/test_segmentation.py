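"""Dice evaluation, fold assignment, and the two segmenters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctatrophy.imgio import CTVolume, LabelVolume, SliceStack
from ctatrophy.phantom import PhantomParams, generate_phantom
from ctatrophy.segmentation import (
    SegmenterConfig,
    default_thresholds,
    dice,
    make_folds,
    multiclass_dice,
    predict_labels,
    threshold_segment,
    train_segmenter,
)


class TestDice:
    def test_identical_masks_score_one(self):
        m = np.zeros((4, 4), bool)
        m[1:3, 1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = b[3, 3] = True
        assert dice(a, b) == 0.0

    def test_hand_counted_overlap(self):
        # |X| = 4, |Y| = 4, |X n Y| = 2 -> 2*2 / 8 = 0.5
        x = np.array([1, 1, 1, 1, 0, 0], bool)
        y = np.array([0, 0, 1, 1, 1, 1], bool)
        assert dice(x, y) == 0.5

    def test_both_empty_raises(self):
        with pytest.raises(ValueError, match="both masks empty"):
            dice(np.zeros(3, bool), np.zeros(3, bool))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice(np.ones((2, 2), bool), np.ones((3, 3), bool))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**30 - 1))
    def test_symmetry_and_bounds_on_random_masks(self, seed):
        r = np.random.default_rng(seed)
        x = r.uniform(size=30) < 0.4
        y = r.uniform(size=30) < 0.4
        if not (x.any() or y.any()):
            x[0] = True
        d = dice(x, y)
        assert d == dice(y, x)
        assert 0.0 <= d <= 1.0
        if d == 1.0:
            assert np.array_equal(x, y)


class TestMulticlassDice:
    def test_identity_prediction(self, noiseless_phantom):
        per_class, mean = multiclass_dice(noiseless_phantom.labels, noiseless_phantom.labels)
        assert per_class == {"CSF": 1.0, "GM": 1.0, "WM": 1.0}
        assert mean == 1.0

    def test_swapped_gm_wm_on_balanced_grid(self):
        truth = np.zeros((1, 4, 4), dtype=int)
        truth[0, 0, :] = 1      # CSF row
        truth[0, 1, :] = 2      # GM row
        truth[0, 2, :] = 3      # WM row
        pred = truth.copy()
        pred[truth == 2] = 3
        pred[truth == 3] = 2
        per_class, _ = multiclass_dice(LabelVolume(pred), LabelVolume(truth))
        assert per_class == {"CSF": 1.0, "GM": 0.0, "WM": 0.0}

    def test_class_missing_from_prediction_scores_zero(self):
        truth = np.zeros((1, 2, 2), dtype=int)
        truth[0, 0, 0] = 1
        truth[0, 0, 1] = 2
        truth[0, 1, 0] = 3
        pred = truth.copy()
        pred[pred == 1] = 2  # CSF entirely absent from prediction
        per_class, _ = multiclass_dice(LabelVolume(pred), LabelVolume(truth))
        assert per_class["CSF"] == 0.0

    def test_class_absent_from_both_excluded_from_mean(self):
        truth = np.zeros((1, 2, 2), dtype=int)
        truth[0, 0] = [2, 3]  # no CSF anywhere
        per_class, mean = multiclass_dice(LabelVolume(truth), LabelVolume(truth))
        assert "CSF" not in per_class
        assert mean == 1.0


class TestMakeFolds:
    def test_leave_one_out_limit(self):
        folds = make_folds(list(range(10)), 10, seed=0)
        sizes = [len(folds.subjects_in_fold(f)) for f in range(10)]
        assert sizes == [1] * 10

    def test_cohort_of_314_into_ten_folds(self):
        folds = make_folds([f"s{i}" for i in range(314)], 10, seed=1)
        sizes = sorted(len(folds.subjects_in_fold(f)) for f in range(10))
        assert set(sizes) == {31, 32}
        assert sum(sizes) == 314

    def test_partition_covers_every_subject_once(self):
        ids = [f"s{i}" for i in range(23)]
        folds = make_folds(ids, 4, seed=2)
        seen = [s for f in range(4) for s in folds.subjects_in_fold(f)]
        assert sorted(seen) == sorted(ids)

    def test_deterministic_under_fixed_seed(self):
        a = make_folds(list(range(50)), 5, seed=9)
        b = make_folds(list(range(50)), 5, seed=9)
        assert a.fold_of_subject == b.fold_of_subject

    def test_more_folds_than_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_folds([1, 2, 3], 5, seed=0)


class TestThresholdSegment:
    def test_noiseless_phantom_recovered_exactly(self, noiseless_phantom):
        thr = default_thresholds(noiseless_phantom.params.tissue_means)
        pred = threshold_segment(noiseless_phantom.ct, noiseless_phantom.brain_mask, thr)
        per_class, mean = multiclass_dice(pred, noiseless_phantom.labels)
        assert mean == 1.0
        assert all(v == 1.0 for v in per_class.values())

    def test_small_noise_keeps_dice_high(self, noisy_phantom):
        thr = default_thresholds(noisy_phantom.params.tissue_means)
        pred = threshold_segment(noisy_phantom.ct, noisy_phantom.brain_mask, thr)
        _, mean = multiclass_dice(pred, noisy_phantom.labels)
        assert mean >= 0.95

    def test_empty_mask_gives_all_background(self, noiseless_phantom):
        pred = threshold_segment(
            noiseless_phantom.ct, np.zeros_like(noiseless_phantom.brain_mask)
        )
        assert np.all(pred.data == 0)

    def test_overlapping_intervals_rejected(self, noiseless_phantom):
        bad = {"CSF": (-np.inf, 20.0), "WM": (15.0, 33.0), "GM": (33.0, np.inf)}
        with pytest.raises(ValueError, match="overlap"):
            threshold_segment(noiseless_phantom.ct, noiseless_phantom.brain_mask, bad)


def _tiny_training_set(n_slices=6, side=16, seed=0):
    from ctatrophy.imgio import window_normalize
    subj = generate_phantom(PhantomParams(grid_shape=(20, side, side), noise_sd=0.0, seed=seed))
    vol = window_normalize(subj.ct)  # network input on the [0, 1] scale
    counts = subj.brain_mask.reshape(20, -1).sum(axis=1)
    keep = np.argsort(-counts)[:n_slices]
    keep.sort()
    return vol.data[keep], subj.labels.data[keep]


class TestTrainableSegmenter:
    def test_overfits_small_noiseless_set(self):
        X, Y = _tiny_training_set()
        cfg = SegmenterConfig(depth=2, base_channels=8, learning_rate=5e-3, batch_size=6,
                              max_epochs=60, early_stop_patience=60,
                              validation_fraction=0.2, seed=0)
        seg = train_segmenter(X, Y, cfg)
        acc = (seg.predict_slice_labels(X) == Y).mean()
        assert acc > 0.95

    def test_zero_epochs_config_is_a_contract_violation(self):
        with pytest.raises(ValueError, match="max_epochs"):
            SegmenterConfig(max_epochs=0)

    def test_shape_depth_incompatibility_rejected_before_training(self):
        X = np.zeros((2, 20, 20))
        Y = np.zeros((2, 20, 20), dtype=int)
        with pytest.raises(ValueError, match="divisible"):
            train_segmenter(X, Y, SegmenterConfig(depth=3))

    def test_training_is_deterministic_for_fixed_seed(self):
        X, Y = _tiny_training_set()
        cfg = SegmenterConfig(depth=2, base_channels=4, learning_rate=1e-3, batch_size=3,
                              max_epochs=3, validation_fraction=0.2, seed=11)
        a = train_segmenter(X, Y, cfg)
        b = train_segmenter(X, Y, cfg)
        assert a.best_val_loss == b.best_val_loss
        assert all(np.array_equal(wa, wb)
                   for wa, wb in zip(a.net.get_weights(), b.net.get_weights()))

    def test_paper_defaults_are_preserved(self):
        cfg = SegmenterConfig()
        assert cfg.learning_rate == 1e-6
        assert cfg.batch_size == 16

    def test_predict_fills_removed_slices_with_background(self):
        X, Y = _tiny_training_set()
        cfg = SegmenterConfig(depth=2, base_channels=4, learning_rate=1e-3, batch_size=3,
                              max_epochs=2, validation_fraction=0.2, seed=0)
        seg = train_segmenter(X, Y, cfg)
        stack = SliceStack(X[:1], [3], n_source_slices=8)
        vol = predict_labels(seg, stack)
        assert vol.data.shape[0] == 8
        others = np.delete(vol.data, 3, axis=0)
        assert np.all(others == 0)

    def test_inference_is_deterministic(self):
        X, Y = _tiny_training_set()
        cfg = SegmenterConfig(depth=2, base_channels=4, learning_rate=1e-3, batch_size=3,
                              max_epochs=2, validation_fraction=0.2, seed=0)
        seg = train_segmenter(X, Y, cfg)
        assert np.array_equal(seg.predict_slice_labels(X), seg.predict_slice_labels(X))

    def test_save_load_round_trip(self, tmp_path):
        X, Y = _tiny_training_set()
        cfg = SegmenterConfig(depth=2, base_channels=4, learning_rate=1e-3, batch_size=3,
                              max_epochs=2, validation_fraction=0.2, seed=0)
        seg = train_segmenter(X, Y, cfg)
        from ctatrophy.segmentation import FittedSegmenter
        path = seg.save(tmp_path / "model.npz")
        back = FittedSegmenter.load(path)
        assert np.array_equal(back.predict_slice_labels(X), seg.predict_slice_labels(X))
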