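"""Time-conditioned CNN classification of embryo crops.

The classifier consumes a square embryo crop plus the developmental
timestamp tau in [0, 1].  tau enters twice: as a constant-valued 4th input
plane alongside the RGB planes, and concatenated to the pooled features at
the final classification layer.  Conditioning on time disambiguates
phenotypes that look alike at different developmental stages.

Training follows a progressive curriculum: the run is divided into steps,
each step adding a larger data fraction and more augmentation groups; the
learning rate is reset to its initial value at the start of every step and
decays by a fixed factor after each epoch.  Class imbalance is handled by
resampling every class to the median non-unknown class count.  At inference,
predictions are averaged over the eight dihedral symmetry variants of the
crop (test-time augmentation); the timestamp plane is unaffected by the
spatial transforms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.transform import rotate as _sk_rotate, resize as _sk_resize

from .detection import crop_embryo
from .nnet import Adam, TimedCNN, build_backbone, softmax
from .taxonomy import ClassTaxonomy, TimeMapping, normalize_time
from .tracking import EmbryoTrack

__all__ = [
    "TimedCrop", "AugConfig", "TrainConfig", "TrackPrediction",
    "balance_training_set", "augment", "draw_augmentation_plan",
    "apply_augmentation_plan", "cross_entropy_loss", "train",
    "dihedral_variants", "tta_predict", "classify_track",
    "save_model", "load_model",
]

AUG_GROUPS = ("hflip", "vflip", "rotation", "crop", "salt_pepper")


@dataclass(frozen=True)
class TimedCrop:
    """A unit-range square crop plus its timestamp tau in [0, 1]."""

    image: np.ndarray  # (H, W) grayscale or (H, W, 3)
    tau: float


@dataclass(frozen=True)
class AugConfig:
    """Which augmentation groups are enabled; one random member of each
    enabled group is applied per example."""

    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.groups) - set(AUG_GROUPS)
        if bad:
            raise ValueError(f"unknown augmentation groups {sorted(bad)}")


def default_aug_schedule(steps: int) -> tuple[tuple[str, ...], ...]:
    """Progressive augmentation schedule: one new group every other step."""
    sched = []
    for s in range(steps):
        sched.append(tuple(AUG_GROUPS[: min(len(AUG_GROUPS), (s + 1) // 2)]))
    return tuple(sched)


@dataclass(frozen=True)
class TrainConfig:
    """Progressive-curriculum training parameters.

    Defaults are the full-scale regime (ResNet18-style backbone, 224-px
    input, batch 350, initial learning rate 1e-3 decayed x0.1 per epoch and
    reset at each step start, 8 steps totalling 152 epochs).  Desk-scale runs
    override backbone/input_size/steps/epochs.
    """

    batch_size: int = 350
    lr: float = 1e-3
    lr_decay: float = 0.1
    steps: int = 8
    epochs_per_step: tuple[int, ...] = (20, 20, 20, 20, 18, 18, 18, 18)
    data_fractions: tuple[float, ...] | None = None  # default: linear ramp to 1
    aug_schedule: tuple[tuple[str, ...], ...] | None = None
    backbone: str = "resnet18_timed"
    input_size: int = 224
    head_pool: str = "max"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.lr <= 0 or not 0 < self.lr_decay <= 1:
            raise ValueError("invalid training hyperparameters")
        if len(self.epochs_per_step) != self.steps:
            raise ValueError("epochs_per_step length must equal steps")

    def resolved_fractions(self) -> tuple[float, ...]:
        if self.data_fractions is not None:
            if len(self.data_fractions) != self.steps:
                raise ValueError("data_fractions length must equal steps")
            return self.data_fractions
        return tuple((s + 1) / self.steps for s in range(self.steps))

    def resolved_aug_schedule(self) -> tuple[tuple[str, ...], ...]:
        if self.aug_schedule is not None:
            if len(self.aug_schedule) != self.steps:
                raise ValueError("aug_schedule length must equal steps")
            return self.aug_schedule
        return default_aug_schedule(self.steps)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v
             for k, v in self.__dict__.items()}, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# class balancing


def balance_training_set(examples: Sequence[tuple[Any, str]],
                         seed: int,
                         unknown_label: str = "unknown",
                         classes: Sequence[str] | None = None) -> list:
    """Resample examples so every class has the median non-unknown count.

    The overrepresented ``unknown`` class is subsampled without replacement;
    every other class is brought to the target by full replication plus a
    seeded random remainder (or subsampled if above it).  Output order is a
    seeded shuffle.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list] = {}
    for ex in examples:
        by_class.setdefault(ex[1], []).append(ex)
    if classes is not None:
        for c in classes:
            if not by_class.get(c):
                raise ValueError(f"class {c!r} has no examples")
    if len(by_class) < 2:
        only = next(iter(by_class), None)
        raise ValueError(
            f"balancing needs at least two classes (got only {only!r})")
    non_unknown = [len(v) for c, v in by_class.items() if c != unknown_label]
    if not non_unknown:
        raise ValueError("no non-unknown classes to balance against")
    target = int(np.median(non_unknown))
    out: list = []
    for c in sorted(by_class):
        items = by_class[c]
        if len(items) >= target:
            idx = rng.choice(len(items), size=target, replace=False)
            out.extend(items[i] for i in sorted(idx))
        else:
            reps, rem = divmod(target, len(items))
            out.extend(items * reps)
            idx = rng.choice(len(items), size=rem, replace=False)
            out.extend(items[i] for i in sorted(idx))
    perm = rng.permutation(len(out))
    return [out[i] for i in perm]


# ---------------------------------------------------------------------------
# augmentation


def draw_augmentation_plan(aug: AugConfig, rng: np.random.Generator) -> dict:
    """Draw one random member of every enabled group."""
    plan: dict = {}
    for group in aug.groups:
        if group == "hflip":
            plan["hflip"] = bool(rng.integers(0, 2))
        elif group == "vflip":
            plan["vflip"] = bool(rng.integers(0, 2))
        elif group == "rotation":
            plan["rotation_deg"] = int(rng.integers(1, 91))  # 1..90, 1-deg steps
        elif group == "crop":
            frac = float(rng.uniform(0.75, 1.0))
            plan["crop"] = (frac, float(rng.random()), float(rng.random()))
        elif group == "salt_pepper":
            plan["salt_pepper"] = (float(rng.uniform(0.0, 0.01)),
                                   int(rng.integers(0, 2**31)))
    return plan


def apply_augmentation_plan(image: np.ndarray, plan: dict) -> np.ndarray:
    out = image
    if plan.get("hflip"):
        out = np.flip(out, axis=1)
    if plan.get("vflip"):
        out = np.flip(out, axis=0)
    if "rotation_deg" in plan:
        out = _sk_rotate(out, plan["rotation_deg"], mode="edge",
                         preserve_range=True)
    if "crop" in plan:
        frac, fx, fy = plan["crop"]
        h, w = out.shape[:2]
        ch, cw = max(8, int(round(h * frac))), max(8, int(round(w * frac)))
        y0 = int(round((h - ch) * fy))
        x0 = int(round((w - cw) * fx))
        out = _sk_resize(out[y0: y0 + ch, x0: x0 + cw], (h, w),
                         order=1, mode="edge", anti_aliasing=False)
    if "salt_pepper" in plan:
        fraction, subseed = plan["salt_pepper"]
        if fraction > 0:
            sub = np.random.default_rng(subseed)
            out = out.copy()
            mask = sub.random(out.shape[:2]) < fraction
            vals = sub.integers(0, 2, int(mask.sum())).astype(float)
            if out.ndim == 3:
                out[mask] = vals[:, None]
            else:
                out[mask] = vals
    return np.ascontiguousarray(out)


def augment(crop: TimedCrop | np.ndarray, aug: AugConfig,
            seed: int | np.random.Generator) -> TimedCrop | np.ndarray:
    """Apply one random member of each enabled group; seeded, tau untouched."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    plan = draw_augmentation_plan(aug, rng)
    if isinstance(crop, TimedCrop):
        return TimedCrop(apply_augmentation_plan(crop.image, plan), crop.tau)
    return apply_augmentation_plan(crop, plan)


# ---------------------------------------------------------------------------
# loss


def cross_entropy_loss(probs: np.ndarray, true_idx: Sequence[int],
                       floor: float = 1e-12) -> float:
    """L = -(1/n) sum ln p_i over the probabilities assigned to true labels.

    Zero exactly when every true-label probability is 1; probabilities are
    floored at ``floor`` to avoid -inf.
    """
    probs = np.asarray(probs, dtype=float)
    true_idx = np.asarray(true_idx, dtype=int)
    if probs.ndim != 2 or len(true_idx) != probs.shape[0] or len(true_idx) == 0:
        raise ValueError("probs must be (n, C) with one true index per row")
    p = np.maximum(probs[np.arange(len(true_idx)), true_idx], floor)
    return float(-np.mean(np.log(p)))


# ---------------------------------------------------------------------------
# training


def train(dataset: tuple[np.ndarray, np.ndarray, Sequence[str]],
          config: TrainConfig,
          taxonomy: ClassTaxonomy | None = None,
          labels_order: Sequence[str] | None = None,
          model: TimedCNN | None = None) -> tuple[TimedCNN, pd.DataFrame]:
    """Train a backbone on (images, taus, labels) with the progressive schedule.

    ``labels_order`` fixes the output-class order (defaults to the taxonomy's
    flat order restricted to labels present).  Returns the trained model and
    a per-epoch log with columns step/epoch/lr/loss/accuracy.  Raises
    ``RuntimeError`` (with the partial log attached as ``.log``) on a
    non-finite loss.
    """
    images, taus, labels = dataset
    images = np.asarray(images, dtype=float)
    taus = np.asarray(taus, dtype=float)
    taxonomy = taxonomy or ClassTaxonomy()
    if labels_order is None:
        present = set(labels)
        labels_order = [l for l in taxonomy.flatten_labels() if l in present]
    label_idx = {l: i for i, l in enumerate(labels_order)}
    y = np.array([label_idx[l] for l in labels], dtype=int)

    rng = np.random.default_rng(config.seed)
    if model is None:
        model = build_backbone(config.backbone, len(labels_order),
                               config.input_size, seed=config.seed,
                               head_pool=config.head_pool)
    opt = Adam(model.params(), lr=config.lr)
    fractions = config.resolved_fractions()
    aug_sched = config.resolved_aug_schedule()
    n_total = len(y)
    log_rows: list[dict] = []

    for step in range(config.steps):
        n_step = max(1, int(np.ceil(fractions[step] * n_total)))
        aug = AugConfig(aug_sched[step])
        lr = config.lr  # reset at each step start
        for epoch in range(config.epochs_per_step[step]):
            order = rng.permutation(n_step)
            opt.lr = lr
            losses, hits, seen = [], 0, 0
            for start in range(0, n_step, config.batch_size):
                idx = order[start: start + config.batch_size]
                batch = images[idx]
                if aug.groups:
                    batch = np.stack([
                        apply_augmentation_plan(
                            img, draw_augmentation_plan(aug, rng))
                        for img in batch])
                x4 = model.make_input(batch, taus[idx])
                logits = model.forward(x4)
                probs = softmax(logits)
                loss = cross_entropy_loss(probs, y[idx])
                if not np.isfinite(loss):
                    log = pd.DataFrame(log_rows)
                    err = RuntimeError(
                        f"training diverged at step {step} epoch {epoch}: "
                        f"loss={loss}")
                    err.log = log
                    raise err
                model.zero_grad()
                dlogits = (probs.copy() -
                           np.eye(len(labels_order))[y[idx]]) / len(idx)
                model.backward(dlogits)
                opt.step()
                losses.append(loss)
                hits += int((probs.argmax(axis=1) == y[idx]).sum())
                seen += len(idx)
            log_rows.append({"step": step, "epoch": epoch, "lr": lr,
                             "n_examples": n_step,
                             "loss": float(np.mean(losses)),
                             "accuracy": hits / seen})
            lr *= config.lr_decay  # decay after each epoch

    return model, pd.DataFrame(
        log_rows, columns=["step", "epoch", "lr", "n_examples",
                           "loss", "accuracy"])


# ---------------------------------------------------------------------------
# test-time augmentation


def dihedral_variants(image: np.ndarray) -> list[np.ndarray]:
    """The 8 symmetry variants of a square image (the dihedral group of the
    square): the four 90-degree rotations and the four rotated mirror
    images.  Each group element appears exactly once."""
    rots = [np.rot90(image, k, axes=(0, 1)) for k in range(4)]
    flipped = np.flip(image, axis=1)
    mirrors = [np.rot90(flipped, k, axes=(0, 1)) for k in range(4)]
    return [np.ascontiguousarray(v) for v in rots + mirrors]


def tta_predict(model, crop: TimedCrop) -> np.ndarray:
    """Average class probabilities over the 8 dihedral variants of the crop.

    The timestamp plane is constant, so spatial transforms leave it
    unchanged.  ``model`` needs only a ``predict_proba(images, taus)``
    method, allowing mock models in tests.
    """
    variants = dihedral_variants(np.asarray(crop.image, dtype=float))
    taus = np.full(len(variants), crop.tau)
    probs = model.predict_proba(np.stack(variants), taus)
    return np.asarray(probs, dtype=float).mean(axis=0)


# ---------------------------------------------------------------------------
# track classification


@dataclass
class TrackPrediction:
    """Per-frame probabilities and argmax labels for one track."""

    track_id: int
    frames: list[int]
    probs: np.ndarray  # (n_frames, n_classes)
    labels: list[str]
    labels_order: list[str] = field(default_factory=list)


def classify_track(model: TimedCNN, track: EmbryoTrack,
                   frames: Mapping[int, Any],
                   time_mapping: TimeMapping | None = None,
                   labels_order: Sequence[str] | None = None,
                   pad_margin_frac: float = 0.25,
                   start_hpf: float | None = None) -> TrackPrediction:
    """Classify every tracked frame of one embryo with TTA.

    ``frames`` maps frame_index -> PlateFrame; gap frames (no detection)
    yield no prediction.  The acquisition clock is anchored at
    ``start_hpf`` (default: the mapping's t0, i.e. imaging starts at the
    early anchor).  Argmax ties resolve to the first label in taxonomy
    order.
    """
    time_mapping = time_mapping or TimeMapping()
    if start_hpf is None:
        start_hpf = time_mapping.t0_hpf
    if labels_order is None:
        labels_order = [str(i) for i in range(model.n_classes)]
    out_frames: list[int] = []
    all_probs: list[np.ndarray] = []
    labels: list[str] = []
    for frame_index, det in track.detections:
        frame = frames.get(frame_index)
        if frame is None:
            continue
        patch = crop_embryo(frame, det, model.input_size, pad_margin_frac)
        t_hpf = start_hpf + frame.acquisition_time_s / 3600.0
        tau = normalize_time(t_hpf, time_mapping)
        p = tta_predict(model, TimedCrop(patch, tau))
        out_frames.append(frame_index)
        all_probs.append(p)
        labels.append(labels_order[int(np.argmax(p))])
    probs = np.array(all_probs) if all_probs else np.zeros((0, model.n_classes))
    return TrackPrediction(track.track_id, out_frames, probs, labels,
                           list(labels_order))


# ---------------------------------------------------------------------------
# persistence


def save_model(model: TimedCNN, directory: str | Path,
               labels_order: Sequence[str],
               time_mapping: TimeMapping | None = None,
               train_config: TrainConfig | None = None) -> None:
    """Model directory: weights plus a JSON sidecar recording the taxonomy
    labels, input size, time mapping and training-config hash."""
    tm = time_mapping or TimeMapping()
    extra = {"labels_order": list(labels_order),
             "time_mapping": {"t0_hpf": tm.t0_hpf, "t1_hpf": tm.t1_hpf}}
    if train_config is not None:
        extra["train_config_hash"] = train_config.config_hash()
    model.save(directory, sidecar_extra=extra)


def load_model(directory: str | Path) -> tuple[TimedCNN, list[str], TimeMapping]:
    model, meta = TimedCNN.load(directory)
    tm = TimeMapping(**meta.get("time_mapping", {}))
    return model, list(meta.get("labels_order", [])), tm
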