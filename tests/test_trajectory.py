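"""Transition-constrained label-sequence correction: DP vs oracle, recovery."""

import numpy as np
import pytest

from embryoscreen.phantom import corrupt_labels
from embryoscreen.taxonomy import ClassTaxonomy
from embryoscreen.trajectory import (
    brute_force_oracle,
    candidate_key,
    candidate_sequence,
    correct_plate,
    correct_severity,
    correct_track,
    is_valid_transition_sequence,
)

U, N, D = "unknown", "normal", "dead"


@pytest.fixture(scope="module")
def tax():
    return ClassTaxonomy(tiered_classes=())


class TestCorrectTrack:
    def test_valid_sequence_is_fixed_point(self, tax):
        raw = [U, U, N, N, N]
        tc = correct_track(raw, tax)
        assert tc.corrected_labels == raw
        assert tc.cost == 0

    def test_single_outlier_repaired(self, tax):
        raw = [U, U, "nodal_lof", U, "nodal_lof", "nodal_lof", D, D]
        tc = correct_track(raw, tax)
        assert tc.cost == 1
        min_cost, argmin = brute_force_oracle(raw, tax)
        assert min_cost == 1
        assert (tc.t1, tc.t2, "nodal_lof" if tc.final_class == "nodal_lof"
                else tc.final_class) in [(t1, t2, x) for t1, t2, x in argmin]
        assert tc.final_class == "nodal_lof"
        assert is_valid_transition_sequence(tc.corrected_labels, tax)

    def test_fewer_transitions_tie_break(self, tax):
        # [N,N,N,N] and [N,N,D,D] both cost 1; fewer transitions wins
        tc = correct_track([N, N, D, N], tax)
        assert tc.corrected_labels == [N, N, N, N]
        assert tc.cost == 1

    def test_all_dead_track_valid(self, tax):
        tc = correct_track([D] * 5, tax)
        assert tc.corrected_labels == [D] * 5
        assert tc.cost == 0
        assert tc.final_class == D

    def test_unknown_to_dead_without_phenotype(self, tax):
        tc = correct_track([U, U, U, D, D], tax)
        assert tc.corrected_labels == [U, U, U, D, D]
        assert tc.final_class == D

    def test_label_outside_taxonomy_rejected(self, tax):
        with pytest.raises(ValueError):
            correct_track(["mystery"], tax)

    def test_idempotence(self, tax):
        rng = np.random.default_rng(8)
        pool = [U, N, D, "wnt_lof", "fgf_lof"]
        for _ in range(50):
            raw = [pool[i] for i in rng.integers(0, len(pool), 30)]
            once = correct_track(raw, tax)
            twice = correct_track(once.corrected_labels, tax)
            assert twice.corrected_labels == once.corrected_labels
            assert twice.cost == 0

    def test_no_unknown_mode_starts_at_frame_zero(self, tax):
        raw = [U, U, "wnt_lof", "wnt_lof", "wnt_lof"]
        tc = correct_track(raw, tax, no_unknown=True)
        assert tc.t1 == 0
        assert tc.corrected_labels == ["wnt_lof"] * 5

    def test_probabilistic_cost_mode(self, tax):
        order = [U, N, D]
        # frame 1's argmax is normal but with low confidence; unknown nearly ties
        probs = np.array([[0.9, 0.05, 0.05],
                          [0.49, 0.51, 0.0],
                          [0.9, 0.05, 0.05],
                          [0.05, 0.9, 0.05]])
        raw = [order[i] for i in probs.argmax(1)]
        tc = correct_track(raw, tax, probs=probs, labels_order=order)
        assert is_valid_transition_sequence(tc.corrected_labels, tax)
        assert tc.corrected_labels == [U, U, U, N]


class TestOracleEquivalence:
    def test_dp_matches_oracle_on_random_tracks(self, tax):
        """On 1,000 random sequences (T <= 60, 6 classes) the scan's cost
        equals the exhaustive minimum, its candidate is in the argmin set,
        and it is the argmin-set optimum under the documented tie policy."""
        rng = np.random.default_rng(42)
        pool = [U, N, D, "wnt_lof", "fgf_lof", "bmp_lof"]
        phen = list(tax.phenotype_classes)
        for _ in range(1000):
            T = int(rng.integers(1, 61))
            raw = [pool[i] for i in rng.integers(0, len(pool), T)]
            tc = correct_track(raw, tax)
            min_cost, argmin = brute_force_oracle(raw, tax)
            assert tc.cost == min_cost
            assert (tc.t1, tc.t2) in {(t1, t2) for t1, t2, _ in argmin}
            # tie policy: the scan's key is minimal over the full argmin set
            keys = [candidate_key(min_cost, T, t1, t2, phen.index(x))
                    for t1, t2, x in argmin]
            chosen = candidate_key(
                min_cost, T, tc.t1, tc.t2,
                phen.index(tc.final_class) if tc.t2 > tc.t1 else 0)
            assert chosen == min(keys)
            assert is_valid_transition_sequence(tc.corrected_labels, tax)

    def test_candidate_sequence_structure(self):
        assert candidate_sequence(5, 2, 4, N) == [U, U, N, N, D]
        assert candidate_sequence(3, 0, 0, N) == [D, D, D]
        assert candidate_sequence(3, 3, 3, N) == [U, U, U]


class TestCorrectSeverity:
    def test_modal_tier(self, taxonomy):
        corrected = ["bmp_lof"] * 3
        raw = ["bmp_lof_weak", "bmp_lof_weak", "bmp_lof_severe"]
        assert correct_severity(corrected, raw, taxonomy) == "weak"

    def test_tie_goes_to_more_severe(self, taxonomy):
        corrected = ["bmp_lof"] * 2
        raw = ["bmp_lof_weak", "bmp_lof_severe"]
        assert correct_severity(corrected, raw, taxonomy) == "severe"

    def test_untier_class_unset(self, taxonomy):
        assert correct_severity(["wnt_lof"] * 3, ["wnt_lof"] * 3,
                                taxonomy) is None

    def test_no_tiered_frames_warns(self, taxonomy):
        with pytest.warns(UserWarning, match="severity left unset"):
            out = correct_severity(["nodal_lof"] * 3, [U, U, U], taxonomy,
                                   final_class="nodal_lof")
        assert out is None

    def test_tiered_raw_track_end_to_end(self, taxonomy):
        raw = [U, U, "nodal_lof_intermediate", "nodal_lof_weak",
               "nodal_lof_intermediate"]
        tc = correct_track(raw, taxonomy)
        assert tc.final_class == "nodal_lof"
        assert tc.severity == "intermediate"


class TestCorrectPlate:
    def test_zero_tracks(self, tax):
        results, df = correct_plate([], tax)
        assert results == [] and df.empty

    def test_ground_truth_is_cost_zero_fixed_point(self, tax):
        preds = [(i, [U] * 3 + ["fgf_lof"] * 5) for i in range(4)]
        results, df = correct_plate(preds, tax)
        assert all(tc.cost == 0 for tc in results)
        assert list(df.final_class) == ["fgf_lof"] * 4

    def test_correction_recovers_corrupted_tracks(self, tax):
        """Piecewise-constant truths corrupted at flip_rate <= 0.2 recover
        the final class in >= 99 % of tracks and place transitions within
        3 frames of truth in >= 95 %, across 20 seeds (T = 200)."""
        pool = [U, N, D, "wnt_lof", "fgf_lof", "bmp_lof"]
        ok_final = ok_trans = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            for _ in range(5):
                t1 = int(rng.integers(20, 120))
                t2 = int(rng.integers(t1, 201))
                x = pool[3:][int(rng.integers(0, 3))]
                truth = candidate_sequence(200, t1, t2, x)
                noisy = corrupt_labels(truth, 0.15, rng, label_set=pool)
                tc = correct_track(noisy, tax)
                truth_final = x if t2 > t1 else (D if t2 < 200 else U)
                ok_final += tc.final_class == truth_final
                if t2 > t1:
                    ok_trans += abs(tc.t1 - t1) <= 3 and abs(tc.t2 - t2) <= 3
                else:
                    ok_trans += abs(tc.t2 - t2) <= 3
                total += 1
        assert ok_final / total >= 0.99
        assert ok_trans / total >= 0.95

    def test_correction_never_hurts_on_average(self, tax):
        """Per-frame accuracy after correction >= before, on >= 95 % of
        corrupted tracks over 20 seeds (flip rate 0.15)."""
        pool = [U, N, D, "wnt_lof", "fgf_lof"]
        improved = total = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            for _ in range(5):
                t1 = int(rng.integers(10, 60))
                t2 = int(rng.integers(t1, 101))
                truth = candidate_sequence(100, t1, t2, "wnt_lof")
                noisy = corrupt_labels(truth, 0.15, rng, label_set=pool)
                tc = correct_track(noisy, tax)
                before = np.mean([a == b for a, b in zip(noisy, truth)])
                after = np.mean([a == b for a, b in
                                 zip(tc.corrected_labels, truth)])
                improved += after >= before
                total += 1
        assert improved / total >= 0.95
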