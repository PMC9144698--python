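"""Iterative weakly supervised training, supervised baselines, k-fold CV.

The weak-supervision loop alternates two steps: train the network for a few
epochs on the current pseudo-masks under the masked loss, then replace each
refinable image's pseudo-mask by the network's own thresholded prediction,
clipped so no positive survives outside the annotated boxes.  Images whose
target is a trusted human mask (``fixed_target=True``) train with a uniform
loss weight and are never rewritten — mixing both supervision sources in
every batch.  Training stops early once the validation loss has failed to
improve for a configurable number of consecutive iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .domain import AnnotatedImage, DatasetSplit, box_union_mask, clip_mask_to_boxes
from .initializers import InitializerConfig, initialize_targets
from .loss_mask import (BCE_EPS, LossMaskParams, loss_mask_for_image, masked_loss,
                        training_loss_params)
from .nn import Adam, DTYPE
from .pipeline import AugmentConfig, augment, compute_dataset_stats
from .unet import UNet, UNetConfig, sigmoid, tiny_config

__all__ = [
    "TrainingSchedule",
    "TrainedModel",
    "refine_targets",
    "run_weakly_supervised_training",
    "run_supervised_training",
    "train_variant",
    "cross_validate",
    "default_schedule",
    "full_sup_3_schedule",
    "VARIANTS",
]

#: minimum decrease of the validation loss that counts as an improvement
EARLY_STOP_TOL = 1e-5

VARIANTS = ("full-sup", "weak-ci", "weak-pi", "weak-hi", "weak-mix")


@dataclass
class TrainingSchedule:
    """Iteration/epoch/learning-rate plan.

    The default follows the published schedule: batch size 12, 3 epochs per
    iteration for the first 2 iterations then 6 epochs for another 6,
    Adam at 1e-4 with inverse-time decay ``lr_e = lr0 / (1 + 5e-4 * e)``
    applied per epoch from the third iteration on, and early stopping after
    2 iterations without validation improvement.
    """

    epochs_per_iteration: list = field(default_factory=lambda: [3, 3, 6, 6, 6, 6, 6, 6])
    batch_size: int = 12
    initial_lr: float = 1e-4
    lr_decay: float = 5e-4
    decay_start_iteration: int = 3  # 1-based ordinal of the first decaying iteration
    early_stop_patience_iterations: int = 2
    refine_threshold: float = 0.5
    reset_optimizer_each_iteration: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.epochs_per_iteration or any(e <= 0 for e in self.epochs_per_iteration):
            raise ValueError("epochs_per_iteration must be non-empty with positive entries")
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")


def default_schedule(**overrides) -> TrainingSchedule:
    return TrainingSchedule(**overrides)


def full_sup_3_schedule(seed: int = 0) -> TrainingSchedule:
    """Fine-tuning preset: 30 epochs, batch 1, lr 1e-4 decaying 5e-4 per epoch."""
    return TrainingSchedule(
        epochs_per_iteration=[30],
        batch_size=1,
        initial_lr=1e-4,
        lr_decay=5e-4,
        decay_start_iteration=1,
        seed=seed,
    )


@dataclass
class TrainedModel:
    """A network bundled with the preprocessing it was trained under."""

    net: UNet
    norm_mean: tuple
    norm_std: tuple
    threshold: float = 0.5

    def _normalize(self, pixels: np.ndarray) -> np.ndarray:
        mean = np.asarray(self.norm_mean)
        std = np.asarray(self.norm_std)
        std = np.where(std > 0, std, 1.0)
        return ((pixels - mean) / std).transpose(2, 0, 1).astype(DTYPE)

    def predict_proba(self, image) -> np.ndarray:
        """Probability map (H, W) for one AnnotatedImage or (H, W, 3) array."""
        pixels = image.pixels if isinstance(image, AnnotatedImage) else np.asarray(image)
        x = self._normalize(pixels)[None]
        logits = self.net.predict_logits(x, batch_size=1)[0]
        return sigmoid(logits)

    def predict_mask(self, image) -> np.ndarray:
        return (self.predict_proba(image) > self.threshold).astype(np.uint8)

    def save(self, path) -> None:
        import json

        self.net.save(path)
        meta = {"norm_mean": list(self.norm_mean), "norm_std": list(self.norm_std),
                "threshold": self.threshold}
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        import json
        import os

        net = UNet.load(path)
        meta_path = str(path) + ".meta.json"
        if os.path.exists(meta_path):
            with open(meta_path) as fh:
                meta = json.load(fh)
        else:
            meta = {"norm_mean": [0.0] * 3, "norm_std": [1.0] * 3, "threshold": 0.5}
        return cls(net=net, norm_mean=tuple(meta["norm_mean"]),
                   norm_std=tuple(meta["norm_std"]), threshold=meta["threshold"])


# ------------------------------------------------------------ refinement

def refine_targets(model: TrainedModel, images: Sequence[AnnotatedImage],
                   threshold: float = 0.5) -> list:
    """Replace every refinable image's target by the thresholded, box-clipped
    model prediction; fixed-target images are returned untouched.  An
    all-negative refined target is allowed (reported in the returned stats
    attached to the function call site)."""
    for im in images:
        if im.fixed_target:
            continue
        prob = model.predict_proba(im)
        new_target = clip_mask_to_boxes((prob > threshold).astype(np.uint8), im.boxes)
        im.target = new_target
    return list(images)


# ------------------------------------------------------- internal helpers

def _seed_streams(seed: int) -> dict:
    """Single run seed -> named independent generators (documented scheme:
    SeedSequence children in fixed order init/shuffle/augment)."""
    ss = np.random.SeedSequence(seed)
    init_ss, shuffle_ss, augment_ss = ss.spawn(3)
    return {
        "init_seed": int(init_ss.generate_state(1)[0] % (2 ** 31)),
        "shuffle": np.random.default_rng(shuffle_ss),
        "augment": np.random.default_rng(augment_ss),
    }


class _TrainSet:
    """Normalized tensors for a list of images, kept in sync with targets."""

    def __init__(self, images: Sequence[AnnotatedImage], mean, std,
                 loss_params: LossMaskParams):
        self.images = list(images)
        mean = np.asarray(mean)
        std = np.where(np.asarray(std) > 0, np.asarray(std), 1.0)
        self.X = np.stack(
            [((im.pixels - mean) / std).transpose(2, 0, 1) for im in images]
        ).astype(DTYPE)
        self.M = np.stack([
            np.ones(im.pixels.shape[:2]) if im.fixed_target
            else loss_mask_for_image(im.boxes, im.width, im.height, loss_params)
            for im in images
        ]).astype(DTYPE)
        self.refresh_targets()

    def refresh_targets(self) -> None:
        self.T = np.stack([im.target for im in self.images]).astype(DTYPE)

    def __len__(self) -> int:
        return len(self.images)


def _lr_for_epoch(schedule: TrainingSchedule, iteration: int, decay_epochs: int) -> float:
    if iteration + 1 < schedule.decay_start_iteration:
        return schedule.initial_lr
    return schedule.initial_lr / (1.0 + schedule.lr_decay * decay_epochs)


def _train_one_epoch(net: UNet, data: _TrainSet, adam: Adam, batch_size: int,
                     rng: np.random.Generator,
                     augment_cfg: Optional[AugmentConfig],
                     aug_rng: Optional[np.random.Generator],
                     loss_params: LossMaskParams) -> float:
    order = rng.permutation(len(data))
    losses, weights = [], []
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        if augment_cfg is not None and augment_cfg.enabled:
            xb, tb, mb = _augment_batch(data, idx, augment_cfg, aug_rng, loss_params)
        else:
            xb, tb, mb = data.X[idx], data.T[idx], data.M[idx]
        z = net.forward(xb, train=True)
        p = sigmoid(z)
        msum = float(mb.sum())
        if msum <= 0:
            raise ValueError("batch loss-mask weights sum to zero")
        grad = (mb * (p - tb) / msum).astype(DTYPE)
        net.backward(grad)
        adam.step(net.grads())
        losses.append(masked_loss(p, tb, mb))
        weights.append(msum)
    return float(np.average(losses, weights=weights))


def _augment_batch(data: _TrainSet, idx, cfg: AugmentConfig,
                   rng: np.random.Generator, loss_params: LossMaskParams):
    xs, ts, ms = [], [], []
    for i in idx:
        im = data.images[i]
        hwc = data.X[i].transpose(1, 2, 0)
        img, boxes, tgt = augment(hwc, im.boxes, data.T[i].astype(np.uint8), cfg, rng)
        xs.append(img.transpose(2, 0, 1))
        ts.append(tgt)
        if im.fixed_target or not boxes:
            ms.append(np.ones(img.shape[:2]))
        else:
            ms.append(loss_mask_for_image(boxes, img.shape[1], img.shape[0], loss_params))
    return (np.stack(xs).astype(DTYPE), np.stack(ts).astype(DTYPE),
            np.stack(ms).astype(DTYPE))


def _validation_loss(net: UNet, data: _TrainSet, batch_size: int) -> float:
    logits = net.predict_logits(data.X, batch_size=batch_size)
    return masked_loss(sigmoid(logits), data.T, data.M)


# -------------------------------------------------------------- main loops

def _run_iterative(
    data: DatasetSplit,
    schedule: TrainingSchedule,
    loss_params: LossMaskParams,
    model_cfg: Optional[UNetConfig],
    seed: Optional[int],
    augment_cfg: Optional[AugmentConfig],
    refine: bool,
    snapshot_targets: bool,
    init_checkpoint=None,
) -> tuple:
    seed = schedule.seed if seed is None else seed
    streams = _seed_streams(seed)
    mean, std = compute_dataset_stats(data.train)
    net = UNet(model_cfg or tiny_config(), seed=streams["init_seed"])
    if init_checkpoint is not None:
        loaded = UNet.load(init_checkpoint)
        for p, q in zip(net.params(), loaded.params()):
            if p.shape != q.shape:
                raise ValueError(f"init checkpoint shape mismatch: {q.shape} vs {p.shape}")
            p[...] = q
    model = TrainedModel(net=net, norm_mean=mean, norm_std=std,
                         threshold=schedule.refine_threshold)

    train_set = _TrainSet(data.train, mean, std, loss_params)
    val_set = _TrainSet(data.validation, mean, std, loss_params) if data.validation else None

    history = {
        "train_loss": [], "val_loss": [], "lr": [], "iteration_of_epoch": [],
        "target_snapshots": [], "refine_stats": [], "early_stopped": False,
        "iterations_run": 0, "seed": seed,
    }
    adam = Adam(net.params(), lr=schedule.initial_lr)
    decay_epochs = 0
    best_val = np.inf
    bad_iters = 0

    for iteration, n_epochs in enumerate(schedule.epochs_per_iteration):
        if schedule.reset_optimizer_each_iteration and iteration > 0:
            adam = Adam(net.params(), lr=schedule.initial_lr)
        for _ in range(n_epochs):
            lr = _lr_for_epoch(schedule, iteration, decay_epochs)
            if iteration + 1 >= schedule.decay_start_iteration:
                decay_epochs += 1
            adam.lr = lr
            loss = _train_one_epoch(net, train_set, adam, schedule.batch_size,
                                    streams["shuffle"], augment_cfg,
                                    streams["augment"], loss_params)
            history["train_loss"].append(loss)
            history["lr"].append(lr)
            history["iteration_of_epoch"].append(iteration)
        history["iterations_run"] = iteration + 1

        val_loss = None
        if val_set is not None:
            val_loss = _validation_loss(net, val_set, schedule.batch_size)
            history["val_loss"].append(val_loss)

        if refine:
            refinables = [im for im in data.train + data.validation if not im.fixed_target]
            previous = {im.image_id: im.target for im in refinables}
            refine_targets(model, refinables, schedule.refine_threshold)
            # a box is guaranteed to contain a polyp, so a fully empty
            # refined pseudo-mask is certainly wrong: keep the previous
            # target for that image instead of training it toward
            # all-background (the same external-consistency reasoning that
            # justifies clipping)
            # per-image mass-preservation guard: every box is known to
            # contain a polyp, so a refined pseudo-mask that wipes out most
            # of that image's previous mask area reflects an underfit model
            # thresholded at 0.5, not a contour estimate — the same
            # external-consistency reasoning that justifies clipping.  Keep
            # the previous target for that image; a later, better-fitted
            # round replaces it.  Healthy refinements keep or grow the area
            # (ratios ~0.8-1.3) and are never touched.
            n_empty = 0
            n_reverted = 0
            for im in refinables:
                new_area = int(im.target.sum())
                if new_area == 0:
                    n_empty += 1
                prev = previous[im.image_id]
                if prev is not None and prev.sum() > 0 and new_area < 0.25 * prev.sum():
                    im.target = prev
                    n_reverted += 1
            outside = 0
            for im in refinables:
                union = box_union_mask(im.boxes, im.width, im.height)
                outside += int(np.count_nonzero((im.target == 1) & (union == 0)))
            history["refine_stats"].append({
                "iteration": iteration, "empty_targets": n_empty,
                "reverted_targets": n_reverted,
                "positives_outside_boxes": outside,
            })
            train_set.refresh_targets()
            if val_set is not None:
                val_set.refresh_targets()
            if snapshot_targets:
                history["target_snapshots"].append({
                    im.image_id: im.target.copy() for im in data.train
                })

        if val_loss is not None:
            if val_loss < best_val - EARLY_STOP_TOL:
                best_val = val_loss
                bad_iters = 0
            else:
                bad_iters += 1
                if bad_iters >= schedule.early_stop_patience_iterations:
                    history["early_stopped"] = True
                    break
    return model, history


def run_weakly_supervised_training(
    data: DatasetSplit,
    init_cfg: InitializerConfig,
    schedule: TrainingSchedule,
    loss_params: Optional[LossMaskParams] = None,
    model_cfg: Optional[UNetConfig] = None,
    init_model: Optional[TrainedModel] = None,
    augment_cfg: Optional[AugmentConfig] = None,
    seed: Optional[int] = None,
    snapshot_targets: bool = True,
) -> tuple:
    """Full weakly supervised loop; returns ``(TrainedModel, history)``.

    ``init_model`` feeds the prediction/hybrid initializers.  Every
    refinable training/validation image must carry at least one box.
    History records per-epoch losses, per-iteration validation losses,
    target snapshots (mask-evolution panels) and the per-image
    initialization log under ``init_log``.
    """
    for im in list(data.train) + list(data.validation):
        if not im.fixed_target and not im.boxes:
            raise ValueError(f"{im.image_id}: refinable image has no boxes")
    if loss_params is None:
        loss_params = training_loss_params()
    predict = init_model.predict_proba if init_model is not None else None
    init_log = initialize_targets(list(data.train) + list(data.validation), init_cfg, predict)
    model, history = _run_iterative(
        data, schedule, loss_params, model_cfg, seed, augment_cfg,
        refine=True, snapshot_targets=snapshot_targets,
    )
    history["init_log"] = init_log
    return model, history


def run_supervised_training(
    data: DatasetSplit,
    schedule: TrainingSchedule,
    model_cfg: Optional[UNetConfig] = None,
    init_checkpoint=None,
    augment_cfg: Optional[AugmentConfig] = None,
    seed: Optional[int] = None,
) -> tuple:
    """Standard training on ground-truth masks (uniform loss weight).

    ``init_checkpoint`` loads starting weights from a saved model (the
    fine-tuning preset that transfers a mixed-supervision model onto a new
    dataset uses this together with :func:`full_sup_3_schedule`)."""
    for im in data.train:
        if im.gt_mask is None:
            raise ValueError(f"{im.image_id}: supervised training requires gt_mask")
        im.target = im.gt_mask.copy()
        im.fixed_target = True
    for im in data.validation:
        if im.gt_mask is None:
            raise ValueError(f"{im.image_id}: supervised validation requires gt_mask")
        im.target = im.gt_mask.copy()
        im.fixed_target = True
    return _run_iterative(
        data, schedule, LossMaskParams(), model_cfg, seed, augment_cfg,
        refine=False, snapshot_targets=False, init_checkpoint=init_checkpoint,
    )


def _as_refinable(images: Sequence[AnnotatedImage]) -> list:
    out = []
    for im in images:
        out.append(AnnotatedImage(
            image_id=im.image_id, pixels=im.pixels, boxes=list(im.boxes),
            gt_mask=im.gt_mask, target=None, fixed_target=False, tags=im.tags,
        ))
    return out


def train_variant(
    data: DatasetSplit,
    variant: str,
    schedule: TrainingSchedule,
    model_cfg: Optional[UNetConfig] = None,
    init_model: Optional[TrainedModel] = None,
    loss_params: Optional[LossMaskParams] = None,
    init_cfg: Optional[InitializerConfig] = None,
    init_checkpoint=None,
    augment_cfg: Optional[AugmentConfig] = None,
    seed: Optional[int] = None,
) -> tuple:
    """Run one named training preset on a data split.

    ``full-sup`` trains on ground-truth masks; ``weak-ci``/``weak-pi``/
    ``weak-hi`` are box-only with circle/prediction/hybrid initialization
    (ground truth, if present, is ignored during training); ``weak-mix``
    keeps the targets of mask-labeled (fixed) images and refines the rest,
    and requires at least one fixed image.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if variant == "full-sup":
        sup_data = DatasetSplit(
            [_copy_im(im) for im in data.train],
            [_copy_im(im) for im in data.validation],
            list(data.test), data.fold_index)
        return run_supervised_training(
            sup_data, schedule, model_cfg, init_checkpoint=init_checkpoint,
            augment_cfg=augment_cfg, seed=seed)

    if variant == "weak-mix":
        if not any(im.fixed_target for im in data.train):
            raise ValueError("weak-mix needs at least one mask-labeled (fixed) training image")
        weak_data = data
        default_strategy = "hybrid" if init_model is not None else "circle"
    else:
        weak_data = DatasetSplit(_as_refinable(data.train), _as_refinable(data.validation),
                                 list(data.test), data.fold_index)
        default_strategy = {"weak-ci": "circle", "weak-pi": "prediction", "weak-hi": "hybrid"}[variant]
    cfg = init_cfg or InitializerConfig(strategy=default_strategy)
    return run_weakly_supervised_training(
        weak_data, cfg, schedule, loss_params, model_cfg, init_model,
        augment_cfg=augment_cfg, seed=seed)


def _copy_im(im: AnnotatedImage) -> AnnotatedImage:
    return AnnotatedImage(
        image_id=im.image_id, pixels=im.pixels, boxes=list(im.boxes),
        gt_mask=im.gt_mask, target=None if im.target is None else im.target.copy(),
        fixed_target=im.fixed_target, tags=im.tags,
    )


# ----------------------------------------------------------- cross-validation

def make_folds(image_ids: Sequence[str], k: int, seed: int) -> list:
    """Deterministic seeded k-fold partition by image id; folds are disjoint,
    cover all ids, and differ in size by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = sorted(image_ids)
    if len(ids) < k:
        raise ValueError(f"cannot split {len(ids)} items into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(ids[idx])
    return [sorted(f) for f in folds]


def cross_validate(
    dataset: Sequence[AnnotatedImage],
    k: int,
    variant: str,
    seed: int = 0,
    schedule: Optional[TrainingSchedule] = None,
    model_cfg: Optional[UNetConfig] = None,
    init_model: Optional[TrainedModel] = None,
    loss_params: Optional[LossMaskParams] = None,
    val_fraction: float = 0.0,
    mix_fraction: float = 0.0,
    threshold: float = 0.5,
) -> dict:
    """k-fold cross-validation of one training variant.

    Trains ``k`` independent models, each tested on a different fold;
    reports per-fold dice/accuracy plus their mean and standard error.
    """
    from .metrics import evaluate_set  # local import to avoid cycle at module load

    schedule = schedule or default_schedule()
    by_id = {im.image_id: im for im in dataset}
    folds = make_folds(list(by_id), k, seed)
    fold_reports = []
    for fold_index, test_ids in enumerate(folds):
        if not test_ids:
            raise ValueError(f"fold {fold_index} has an empty test set")
        test = [by_id[i] for i in test_ids]
        train_pool = [_copy_im(by_id[i]) for j, f in enumerate(folds) if j != fold_index for i in f]
        rng = np.random.default_rng(seed + fold_index)
        n_val = int(round(val_fraction * len(train_pool)))
        order = rng.permutation(len(train_pool))
        validation = [train_pool[i] for i in order[:n_val]]
        train = [train_pool[i] for i in order[n_val:]]
        if variant == "weak-mix" and mix_fraction > 0:
            n_fixed = max(1, int(round(mix_fraction * len(train))))
            for im in train[:n_fixed]:
                if im.gt_mask is None:
                    raise ValueError(f"{im.image_id}: mix labeling requires gt_mask")
                im.fixed_target = True
                im.target = im.gt_mask.copy()
        split = DatasetSplit(train, validation, test, fold_index)
        model, _ = train_variant(split, variant, schedule, model_cfg, init_model,
                                 loss_params, seed=seed + fold_index)
        report = evaluate_set(model, test, threshold=threshold)
        report["fold_index"] = fold_index
        fold_reports.append(report)
    dices = np.array([r["mean_dice"] for r in fold_reports])
    accs = np.array([r["mean_accuracy"] for r in fold_reports])
    sem = lambda v: float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return {
        "k": k, "variant": variant, "seed": seed,
        "fold_dice": [float(d) for d in dices],
        "fold_accuracy": [float(a) for a in accs],
        "mean_dice": float(dices.mean()), "sem_dice": sem(dices),
        "mean_accuracy": float(accs.mean()), "sem_accuracy": sem(accs),
        "folds": fold_reports,
    }
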