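"""Determinism, geometry and ground-truth guarantees of the phantom generator."""

import numpy as np
import pytest

from embryoscreen.phantom import (
    EmbryoSchedule,
    PhantomSpec,
    corrupt_labels,
    generate_phantom,
    generate_training_crops,
    oracle_classify,
)
from embryoscreen.taxonomy import ClassTaxonomy


class TestGeneratePhantom:
    def test_seeded_runs_are_byte_identical(self, flat_taxonomy):
        spec = PhantomSpec(seed=11, frames_per_well=3, image_size_px=128,
                           n_embryos_range=(2, 3), radius_px_range=(18, 24))
        a = generate_phantom(spec, flat_taxonomy)
        b = generate_phantom(spec, flat_taxonomy)
        for well in a.frames:
            for fa, fb in zip(a.frames[well], b.frames[well]):
                np.testing.assert_array_equal(fa.pixels, fb.pixels)
        assert a.annotations == b.annotations

    def test_zero_embryos_blank_noisy_frames(self, flat_taxonomy):
        spec = PhantomSpec(seed=0, frames_per_well=2, image_size_px=64,
                           n_embryos_range=(0, 0))
        res = generate_phantom(spec, flat_taxonomy)
        (recs,) = res.annotations.values()
        assert all(not r.embryos for r in recs)
        (frames,) = res.frames.values()
        assert frames[0].pixels.std() > 0  # noise present

    def test_radii_in_range_and_disks_disjoint(self, flat_taxonomy):
        spec = PhantomSpec(seed=5, frames_per_well=1, image_size_px=400,
                           n_embryos_range=(5, 5), radius_px_range=(30, 40))
        res = generate_phantom(spec, flat_taxonomy)
        (recs,) = res.annotations.values()
        embryos = recs[0].embryos
        assert len(embryos) == 5
        for e in embryos:
            assert 30 <= e.radius_px <= 40
        for i, a in enumerate(embryos):
            for b in embryos[i + 1:]:
                d = np.hypot(a.center_x_px - b.center_x_px,
                             a.center_y_px - b.center_y_px)
                assert d > a.radius_px + b.radius_px

    def test_infeasible_packing_raises_before_render(self, flat_taxonomy):
        spec = PhantomSpec(seed=0, frames_per_well=1, image_size_px=100,
                           n_embryos_range=(20, 20), radius_px_range=(30, 40))
        with pytest.raises(ValueError, match="infeasible packing"):
            generate_phantom(spec, flat_taxonomy)

    def test_ground_truth_labels_follow_schedule(self, flat_taxonomy):
        sched = EmbryoSchedule("wnt_lof", onset_frame=4, death_frame=8)
        spec = PhantomSpec(seed=1, frames_per_well=10, image_size_px=128,
                           n_embryos_range=(1, 1), radius_px_range=(20, 25),
                           schedules=((sched,),))
        res = generate_phantom(spec, flat_taxonomy)
        (recs,) = res.annotations.values()
        labels = [r.embryos[0].class_label for r in recs]
        assert labels == (["unknown"] * 4 + ["wnt_lof"] * 4 + ["dead"] * 2)

    def test_onset_after_death_rejected(self):
        with pytest.raises(ValueError):
            EmbryoSchedule("normal", onset_frame=5, death_frame=3)

    def test_severity_attached_for_tiered_classes(self, taxonomy):
        sched = EmbryoSchedule("bmp_lof", onset_frame=1, severity="weak")
        spec = PhantomSpec(seed=1, frames_per_well=3, image_size_px=128,
                           n_embryos_range=(1, 1), radius_px_range=(20, 25),
                           schedules=((sched,),))
        res = generate_phantom(spec, taxonomy)
        (recs,) = res.annotations.values()
        assert recs[2].embryos[0].class_label == "bmp_lof_weak"
        assert recs[2].embryos[0].severity == "weak"


class TestCorruptLabels:
    def test_zero_rate_is_identity(self):
        labels = ["normal"] * 50 + ["dead"] * 50
        assert corrupt_labels(labels, 0.0, 1) == labels

    def test_flipped_labels_are_always_wrong(self):
        labels = ["normal"] * 200
        out = corrupt_labels(labels, 0.9, 2, label_set=["normal", "dead", "unknown"])
        assert all(l in ("normal", "dead", "unknown") for l in out)
        assert any(l != "normal" for l in out)

    def test_single_frame_high_rate_flips_almost_surely(self):
        rate = 0.99
        flips = sum(
            corrupt_labels(["normal"], rate, seed,
                           label_set=["normal", "dead"])[0] != "normal"
            for seed in range(500))
        # Binomial(500, 0.99): 3 sd below the mean is ~488
        assert flips >= 480

    def test_empirical_flip_fraction_matches_rate(self):
        labels = ["normal"] * 1000
        out = corrupt_labels(labels, 0.2, 7, label_set=["normal", "dead", "unknown"])
        frac = np.mean([l != "normal" for l in out])
        assert frac == pytest.approx(0.2, abs=0.03)  # ~2.4 binomial sd

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            corrupt_labels(["a"], 1.0, 0)


class TestOracleSeparability:
    def test_oracle_is_perfect_on_noise_free_renders(self, flat_taxonomy):
        """Every class motif is identifiable from pixels alone post-onset."""
        classes = ("normal", "dead", "bmp_lof", "nodal_lof", "ra_gain",
                   "wnt_lof", "fgf_lof", "shh_lof", "pcp_lof")
        scheds = tuple(EmbryoSchedule(c, onset_frame=0) for c in classes)
        spec = PhantomSpec(seed=2, frames_per_well=1, image_size_px=700,
                           n_embryos_range=(9, 9), radius_px_range=(24, 28),
                           schedules=(scheds,), noise_sigma=0.0,
                           salt_pepper_fraction=0.0, drift_px_per_frame=0.0)
        res = generate_phantom(spec, flat_taxonomy)
        (frames,), (recs,) = res.frames.values(), res.annotations.values()
        img = frames[0].to_float()
        states = ("unknown",) + classes
        for e in recs[0].embryos:
            got = oracle_classify(img, e.center_x_px, e.center_y_px,
                                  e.radius_px, states)
            assert got == e.class_label

    def test_pre_onset_render_is_neutral(self, flat_taxonomy):
        sched = EmbryoSchedule("pcp_lof", onset_frame=5)
        spec = PhantomSpec(seed=2, frames_per_well=1, image_size_px=128,
                           n_embryos_range=(1, 1), radius_px_range=(20, 24),
                           schedules=((sched,),), noise_sigma=0.0,
                           salt_pepper_fraction=0.0)
        res = generate_phantom(spec, flat_taxonomy)
        (frames,), (recs,) = res.frames.values(), res.annotations.values()
        e = recs[0].embryos[0]
        got = oracle_classify(frames[0].to_float(), e.center_x_px,
                              e.center_y_px, e.radius_px,
                              ("unknown", "pcp_lof"))
        assert got == "unknown"


class TestTrainingCrops:
    def test_labels_match_onset_logic(self, flat_taxonomy):
        imgs, taus, labels = generate_training_crops(
            100, 32, ("normal", "dead"), seed=3, taxonomy=flat_taxonomy)
        assert imgs.shape == (100, 32, 32)
        assert set(labels) <= {"unknown", "normal", "dead"}
        assert (taus >= 0).all() and (taus <= 1).all()
        assert "unknown" in labels  # early taus exist at these settings
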