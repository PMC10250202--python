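"""Balancing, augmentation, loss, schedule, TTA and track classification."""

import numpy as np
import pytest
from scipy.stats import chisquare

from embryoscreen.classifier import (
    AugConfig,
    TimedCrop,
    TrainConfig,
    apply_augmentation_plan,
    augment,
    balance_training_set,
    classify_track,
    cross_entropy_loss,
    dihedral_variants,
    draw_augmentation_plan,
    load_model,
    save_model,
    train,
    tta_predict,
)
from embryoscreen.detection import Detection
from embryoscreen.io import PlateFrame
from embryoscreen.nnet import build_backbone
from embryoscreen.phantom import generate_training_crops
from embryoscreen.taxonomy import ClassTaxonomy, TimeMapping
from embryoscreen.tracking import EmbryoTrack


class TestBalanceTrainingSet:
    def test_median_target_policy(self):
        examples = ([("u", "unknown")] * 1000 + [("a", "A")] * 100
                    + [("b", "B")] * 50)
        out = balance_training_set(examples, seed=0)
        counts = {c: sum(1 for _, l in out if l == c)
                  for c in ("unknown", "A", "B")}
        # target = median of non-unknown counts {100, 50} = 75
        assert counts == {"unknown": 75, "A": 75, "B": 75}

    def test_already_balanced_counts_unchanged(self):
        examples = [("a", "A")] * 40 + [("b", "B")] * 40
        out = balance_training_set(examples, seed=1)
        assert sum(1 for _, l in out if l == "A") == 40
        assert sum(1 for _, l in out if l == "B") == 40

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balance_training_set([("a", "A")] * 10, seed=0)

    def test_missing_requested_class_named(self):
        with pytest.raises(ValueError, match="'B'"):
            balance_training_set([("a", "A")] * 5 + [("c", "C")] * 5, seed=0,
                                 classes=["A", "B"])

    def test_seeded_shuffle_deterministic(self):
        examples = [("a", "A")] * 30 + [("b", "B")] * 20
        assert balance_training_set(examples, 5) == balance_training_set(examples, 5)


class TestAugment:
    def test_disabled_groups_identity(self, rng):
        img = rng.random((32, 32))
        out = augment(img, AugConfig(()), 0)
        np.testing.assert_array_equal(out, img)

    def test_seeded_determinism(self, rng):
        img = rng.random((32, 32))
        cfg = AugConfig(("hflip", "vflip", "rotation", "crop", "salt_pepper"))
        np.testing.assert_array_equal(augment(img, cfg, 9), augment(img, cfg, 9))

    def test_rotation_angles_uniform_over_90_values(self):
        rng = np.random.default_rng(123)
        cfg = AugConfig(("rotation",))
        angles = [draw_augmentation_plan(cfg, rng)["rotation_deg"]
                  for _ in range(9000)]
        counts = np.bincount(angles, minlength=91)[1:]
        assert counts.sum() == 9000
        _, p = chisquare(counts)
        assert p > 0.01

    def test_tau_untouched(self, rng):
        crop = TimedCrop(rng.random((16, 16)), 0.42)
        out = augment(crop, AugConfig(("hflip", "rotation")), 3)
        assert out.tau == 0.42

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            AugConfig(("zoom",))


class TestCrossEntropyLoss:
    def test_perfect_batch_is_exactly_zero(self):
        probs = np.eye(3)[[0, 1, 2]]
        assert cross_entropy_loss(probs, [0, 1, 2]) == 0.0

    def test_inverse_e_gives_one(self):
        p = np.full((4, 2), np.exp(-1))
        assert cross_entropy_loss(p, [0, 1, 0, 1]) == pytest.approx(1.0)

    def test_hand_computed_batch(self):
        probs = np.array([[0.5, 0.5], [0.25, 0.75]])
        want = -(np.log(0.5) + np.log(0.25)) / 2  # 1.039720...
        assert cross_entropy_loss(probs, [0, 0]) == pytest.approx(want)
        assert cross_entropy_loss(probs, [0, 0]) == pytest.approx(1.0397208, abs=1e-6)

    def test_zero_probability_floored_not_raising(self):
        loss = cross_entropy_loss(np.array([[0.0, 1.0]]), [0])
        assert np.isfinite(loss) and loss > 0

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.zeros((0, 2)), [])


@pytest.fixture(scope="module")
def toy_run():
    tax = ClassTaxonomy(tiered_classes=())
    imgs, taus, labels = generate_training_crops(
        120, 16, ("normal", "dead"), seed=5, taxonomy=tax)
    cfg = TrainConfig(batch_size=16, steps=2, epochs_per_step=(2, 2),
                      backbone="tinycnn_timed", input_size=16, seed=1,
                      aug_schedule=((), ("hflip",)),
                      data_fractions=(0.5, 1.0))
    model, log = train((imgs, taus, labels), cfg, tax)
    return model, log, cfg


class TestTrainSchedule:

    def test_lr_resets_per_step_and_decays_per_epoch(self, toy_run):
        _, log, cfg = toy_run
        for step in (0, 1):
            lrs = log[log.step == step].lr.tolist()
            assert lrs[0] == pytest.approx(cfg.lr)  # reset at step start
            for a, b in zip(lrs, lrs[1:]):
                assert b == pytest.approx(a * cfg.lr_decay)

    def test_data_fraction_grows(self, toy_run):
        _, log, _ = toy_run
        n0 = log[log.step == 0].n_examples.iloc[0]
        n1 = log[log.step == 1].n_examples.iloc[0]
        assert n0 == 60 and n1 == 120

    def test_zero_epochs_returns_model_unchanged(self):
        tax = ClassTaxonomy(tiered_classes=())
        imgs, taus, labels = generate_training_crops(
            20, 16, ("normal", "dead"), seed=5, taxonomy=tax)
        cfg = TrainConfig(batch_size=8, steps=1, epochs_per_step=(0,),
                          backbone="tinycnn_timed", input_size=16, seed=1)
        before = build_backbone("tinycnn_timed", 3, 16, seed=1)
        ref = [w.copy() for w, _ in before.params()]
        model, log = train((imgs, taus, labels), cfg, tax, model=before)
        assert log.empty
        for (w, _), r in zip(model.params(), ref):
            np.testing.assert_array_equal(w, r)

    def test_training_reduces_loss(self, toy_run):
        _, log, _ = toy_run
        assert log.loss.iloc[-1] < log.loss.iloc[0]


class _ConstantModel:
    """Mock returning one fixed probability vector for any input."""

    def __init__(self, vec):
        self.vec = np.asarray(vec, dtype=float)

    def predict_proba(self, images, taus):
        return np.tile(self.vec, (len(images), 1))


class _OrientationModel:
    """Mock returning a distinct one-hot depending on the corner pixel."""

    def predict_proba(self, images, taus):
        out = np.zeros((len(images), 8))
        for i, img in enumerate(images):
            marks = (img[0, 0] > 0.5, img[0, -1] > 0.5,
                     img[-1, 0] > 0.5, img[-1, -1] > 0.5)
            out[i, marks.index(True)] = 1.0
        return out


class TestTTA:
    def test_eight_distinct_dihedral_variants(self, rng):
        img = rng.random((6, 6))  # asymmetric with probability 1
        variants = dihedral_variants(img)
        assert len(variants) == 8
        keys = {v.tobytes() for v in variants}
        assert len(keys) == 8
        # the set is closed under a further rotation (it is the full group)
        rotated = {np.ascontiguousarray(np.rot90(v)).tobytes()
                   for v in variants}
        assert rotated == keys

    def test_constant_model_fixed_point(self):
        vec = np.array([0.1, 0.2, 0.3, 0.4])
        out = tta_predict(_ConstantModel(vec), TimedCrop(np.zeros((8, 8)), 0.5))
        np.testing.assert_allclose(out, vec)

    def test_orientation_model_averages_one_hots(self):
        img = np.zeros((8, 8))
        img[0, 0] = 1.0  # single marked corner
        out = tta_predict(_OrientationModel(), TimedCrop(img, 0.0))
        # each variant puts the mark in some corner; mean over 8 one-hots
        assert out.sum() == pytest.approx(1.0)
        # the 4 corner classes each receive exactly 2 of the 8 variants
        np.testing.assert_allclose(sorted(out[:4]), [0.25] * 4)

    def test_real_model_output_normalized(self):
        model = build_backbone("tinycnn_timed", 5, 16, seed=2)
        out = tta_predict(model, TimedCrop(np.random.default_rng(0).random((16, 16)), 0.3))
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        # exact identity: TTA equals the mean of the 8 single passes
        singles = [model.predict_proba(v[None], [0.3])[0]
                   for v in dihedral_variants(np.asarray(
                       np.random.default_rng(0).random((16, 16))))]
        np.testing.assert_allclose(out, np.mean(singles, axis=0), atol=1e-12)


class TestClassifyTrack:
    def _frames(self, n, size=32):
        rng = np.random.default_rng(1)
        return {t: PlateFrame((rng.random((size, size)) * 255).astype(np.uint8),
                              t, t * 120.0, "A-01") for t in range(n)}

    def _track(self, frames_present):
        tr = EmbryoTrack(0)
        for t in frames_present:
            tr.detections.append((t, Detection(t, 16.0, 16.0, 8.0, 1.0)))
        return tr

    def test_gap_frame_yields_no_prediction(self):
        model = build_backbone("tinycnn_timed", 3, 16, seed=0)
        frames = self._frames(10)
        track = self._track([t for t in range(10) if t != 4])
        pred = classify_track(model, track, frames, TimeMapping(),
                              ["a", "b", "c"])
        assert len(pred.labels) == 9
        assert 4 not in pred.frames

    def test_constant_model_constant_labels(self):
        frames = self._frames(5)
        track = self._track(range(5))

        class _M(_ConstantModel):
            input_size = 16
            n_classes = 3
        model = _M([0.2, 0.5, 0.3])
        pred = classify_track(model, track, frames, TimeMapping(),
                              ["a", "b", "c"])
        assert pred.labels == ["b"] * 5
        assert np.allclose(pred.probs, [0.2, 0.5, 0.3])


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        model = build_backbone("tinycnn_timed", 4, 16, seed=3)
        save_model(model, tmp_path / "m", ["a", "b", "c", "d"],
                   TimeMapping(), TrainConfig(backbone="tinycnn_timed",
                                              input_size=16))
        back, order, tm = load_model(tmp_path / "m")
        assert order == ["a", "b", "c", "d"]
        assert tm == TimeMapping()
        x = np.random.default_rng(0).random((2, 16, 16))
        np.testing.assert_allclose(model.predict_proba(x, [0.1, 0.9]),
                                   back.predict_proba(x, [0.1, 0.9]))

    def test_resnet_preset_forward_backward(self):
        model = build_backbone("resnet18_timed", 3, 32, seed=0)
        x4 = model.make_input(np.random.default_rng(0).random((1, 32, 32)), [0.5])
        logits = model.forward(x4)
        assert logits.shape == (1, 3)
        model.zero_grad()
        model.backward(np.ones((1, 3)))
        assert model.class_weights.shape == (3, 512)
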