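import numpy as np
import pytest

from boxseg.domain import AnnotatedImage, BoundingBox, DatasetSplit, box_union_mask
from boxseg.initializers import InitializerConfig
from boxseg.synthetic import apply_mix_labels, benchmark_schedule, benchmark_suite
from boxseg.trainer import (
    TrainingSchedule,
    cross_validate,
    full_sup_3_schedule,
    make_folds,
    refine_targets,
    run_supervised_training,
    run_weakly_supervised_training,
    train_variant,
)
from boxseg.unet import UNetConfig


def _tiny32():
    return UNetConfig(depth=2, channel_schedule=(6, 12), convs_per_block=(1, 1),
                      bottleneck_channels=12, input_size=32)


def _blob_images(n=8, size=32, seed=0):
    rng = np.random.default_rng(seed)
    images = []
    for i in range(n):
        pix = rng.random((size, size, 3)) * 0.2
        gt = np.zeros((size, size), dtype=np.uint8)
        cx, cy = rng.integers(10, size - 10, size=2)
        r = rng.integers(4, 7)
        ys, xs = np.mgrid[0:size, 0:size]
        gt[(xs - cx) ** 2 + (ys - cy) ** 2 < r * r] = 1
        pix[gt == 1] += 0.6
        ysn, xsn = np.nonzero(gt)
        box = BoundingBox.from_corner(float(xsn.min()), float(ysn.min()),
                                      float(xsn.max() + 1 - xsn.min()),
                                      float(ysn.max() + 1 - ysn.min()))
        images.append(AnnotatedImage(image_id=f"b{i}", pixels=np.clip(pix, 0, 1),
                                     boxes=[box], gt_mask=gt))
    return images


class _FakeModel:
    def __init__(self, prob_fn):
        self.prob_fn = prob_fn

    def predict_proba(self, image):
        return self.prob_fn(image)


class TestRefineTargets:
    def test_all_positive_prediction_becomes_box_interior(self):
        images = _blob_images(2)
        model = _FakeModel(lambda im: np.ones(im.pixels.shape[:2]))
        refine_targets(model, images)
        for im in images:
            assert np.array_equal(im.target, box_union_mask(im.boxes, im.width, im.height))

    def test_fixed_images_keep_their_mask_bit_identical(self):
        images = _blob_images(2)
        images[0].fixed_target = True
        images[0].target = images[0].gt_mask.copy()
        before = images[0].target.copy()
        model = _FakeModel(lambda im: np.zeros(im.pixels.shape[:2]))
        refine_targets(model, images)
        assert np.array_equal(images[0].target, before)
        assert images[1].target.sum() == 0  # all-negative target is allowed

    def test_positives_outside_boxes_are_clipped(self):
        images = _blob_images(1)

        def instrument_probability(im):
            p = np.zeros(im.pixels.shape[:2])
            p[:, :3] = 0.9  # bright bar at the left edge, outside the box
            p[im.gt_mask == 1] = 0.9
            return p

        refine_targets(_FakeModel(instrument_probability), images)
        im = images[0]
        union = box_union_mask(im.boxes, im.width, im.height)
        assert not np.any((im.target == 1) & (union == 0))
        assert im.target.sum() > 0


class TestScheduleMechanics:
    def test_zero_learning_rate_leaves_weights_unchanged(self):
        images = _blob_images(6)
        split = DatasetSplit(images[:5], [], images[5:])
        schedule = TrainingSchedule(epochs_per_iteration=[1], batch_size=4,
                                    initial_lr=0.0, seed=0)
        model, _ = run_weakly_supervised_training(
            split, InitializerConfig(strategy="circle"), schedule,
            model_cfg=_tiny32())
        fresh, _ = run_weakly_supervised_training(
            DatasetSplit([im for im in _blob_images(6)[:5]], [], []),
            InitializerConfig(strategy="circle"), schedule, model_cfg=_tiny32())
        for p, q in zip(model.net.params(), fresh.net.params()):
            assert np.array_equal(p, q)

    def test_seeded_rerun_reproduces_first_epoch_loss(self):
        images = _blob_images(8)
        split = DatasetSplit(images[:6], [], images[6:])
        schedule = TrainingSchedule(epochs_per_iteration=[1], batch_size=4,
                                    initial_lr=1e-3, seed=3)
        _, h1 = run_weakly_supervised_training(
            split, InitializerConfig(strategy="circle"), schedule, model_cfg=_tiny32())
        split2 = DatasetSplit(_blob_images(8)[:6], [], [])
        _, h2 = run_weakly_supervised_training(
            split2, InitializerConfig(strategy="circle"), schedule, model_cfg=_tiny32())
        assert h1["train_loss"][0] == h2["train_loss"][0]

    def test_early_stopping_on_flat_validation_loss(self):
        images = _blob_images(10)
        split = DatasetSplit(images[:6], images[6:8], images[8:])
        # lr 0: the validation loss can never improve after the first iteration
        schedule = TrainingSchedule(epochs_per_iteration=[1] * 6, batch_size=4,
                                    initial_lr=0.0,
                                    early_stop_patience_iterations=2, seed=0)
        _, history = run_weakly_supervised_training(
            split, InitializerConfig(strategy="circle"), schedule, model_cfg=_tiny32())
        assert history["early_stopped"]
        # frozen weights: after the targets settle the loss cannot improve,
        # so patience (2) runs out well before the 6 scheduled iterations
        assert history["iterations_run"] <= 4

    def test_supervised_loss_trend_is_downward(self):
        images = _blob_images(10, seed=2)
        split = DatasetSplit(images[:8], [], images[8:])
        schedule = TrainingSchedule(epochs_per_iteration=[6], batch_size=4,
                                    initial_lr=3e-3, decay_start_iteration=10, seed=0)
        _, history = run_supervised_training(split, schedule, model_cfg=_tiny32())
        losses = history["train_loss"]
        violations = sum(1 for a, b in zip(losses, losses[1:]) if b >= a)
        assert violations <= 1

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            TrainingSchedule(epochs_per_iteration=[])
        with pytest.raises(ValueError):
            TrainingSchedule(epochs_per_iteration=[2, 0])
        assert full_sup_3_schedule().batch_size == 1
        assert full_sup_3_schedule().epochs_per_iteration == [30]


class TestVariants:
    def test_weak_mix_requires_fixed_images(self):
        images = _blob_images(6)
        split = DatasetSplit(images[:5], [], images[5:])
        with pytest.raises(ValueError, match="mask-labeled"):
            train_variant(split, "weak-mix", TrainingSchedule(
                epochs_per_iteration=[1], batch_size=4, seed=0), model_cfg=_tiny32())

    def test_supervised_requires_gt_masks(self):
        images = _blob_images(4)
        images[0].gt_mask = None
        split = DatasetSplit(images[:3], [], images[3:])
        with pytest.raises(ValueError, match="gt_mask"):
            run_supervised_training(split, TrainingSchedule(
                epochs_per_iteration=[1], batch_size=4), model_cfg=_tiny32())

    def test_refinable_image_without_boxes_rejected(self):
        images = _blob_images(4)
        images[1].boxes = []
        split = DatasetSplit(images[:3], [], images[3:])
        with pytest.raises(ValueError, match="no boxes"):
            run_weakly_supervised_training(
                split, InitializerConfig(strategy="circle"),
                TrainingSchedule(epochs_per_iteration=[1], batch_size=4),
                model_cfg=_tiny32())

    def test_full_sup_3_fine_tunes_from_checkpoint(self, tmp_path):
        images = _blob_images(8)
        split = DatasetSplit(images[:6], [], images[6:])
        pre, _ = run_supervised_training(
            split, TrainingSchedule(epochs_per_iteration=[1], batch_size=4,
                                    initial_lr=1e-3, seed=0), model_cfg=_tiny32())
        path = tmp_path / "mix.npz"
        pre.net.save(path)
        schedule = TrainingSchedule(epochs_per_iteration=[1], batch_size=1,
                                    initial_lr=0.0, seed=1)
        tuned, _ = run_supervised_training(
            DatasetSplit(_blob_images(8)[:6], [], []), schedule,
            model_cfg=_tiny32(), init_checkpoint=path)
        for p, q in zip(tuned.net.params(), pre.net.params()):
            assert np.array_equal(p, q)  # lr 0: starting weights preserved


class TestFolds:
    def test_ten_folds_of_1200_are_disjoint_and_cover(self):
        ids = [f"id{i}" for i in range(1200)]
        folds = make_folds(ids, 10, seed=0)
        assert all(len(f) == 120 for f in folds)
        flat = [i for f in folds for i in f]
        assert sorted(flat) == sorted(ids)

    def test_two_folds_of_four(self):
        folds = make_folds(["a", "b", "c", "d"], 2, seed=1)
        assert sorted(len(f) for f in folds) == [2, 2]

    def test_same_seed_same_partition(self):
        ids = [f"x{i}" for i in range(37)]
        assert make_folds(ids, 5, seed=9) == make_folds(ids, 5, seed=9)

    def test_too_few_items_raises(self):
        with pytest.raises(ValueError):
            make_folds(["a"], 2, seed=0)

    def test_cross_validate_reports_per_fold_scores(self):
        images = _blob_images(10, seed=4)
        schedule = TrainingSchedule(epochs_per_iteration=[2], batch_size=4,
                                    initial_lr=3e-3, decay_start_iteration=10, seed=0)
        report = cross_validate(images, k=2, variant="weak-ci", seed=0,
                                schedule=schedule, model_cfg=_tiny32())
        assert len(report["fold_dice"]) == 2
        assert report["mean_dice"] == pytest.approx(np.mean(report["fold_dice"]))
        assert report["sem_dice"] >= 0


class TestMixedSupervisionStability:
    def test_fixed_targets_identical_across_all_iterations(self, smoke_mix_run):
        history = smoke_mix_run["history"]
        split = smoke_mix_run["split"]
        fixed_ids = {im.image_id for im in split.train if im.fixed_target}
        assert fixed_ids
        gt = {im.image_id: im.gt_mask for im in split.train if im.fixed_target}
        for snap in history["target_snapshots"]:
            for image_id in fixed_ids:
                assert np.array_equal(snap[image_id], gt[image_id])
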