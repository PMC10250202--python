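"""Biologically constrained correction of per-track label sequences.

Early embryos all look alike (class ``unknown``); a phenotype becomes
apparent once, and an embryo can die at any point — but a dead embryo never
recovers and one phenotype never turns into another.  A valid track history
is therefore piecewise constant with at most three segments::

    [unknown) [one phenotype class or normal) [dead)

any of which may be empty.  Given a noisy per-frame label sequence, the
corrector searches all valid candidate histories (every phenotype class X
and every pair of change points 0 <= t1 <= t2 <= T) and selects the one
whose cost — the number of frames where the candidate disagrees with the
raw labels — is minimal.  Outlier frames are replaced by the model label.
Ties are broken by (1) fewer transitions, (2) later first transition,
(3) taxonomy order of X, then deterministically by larger t1 and t2.

The search runs in O(T x C) with prefix sums; an exhaustive O(T^2 x C)
oracle (:func:`brute_force_oracle`) is provided for verification and must
agree exactly.

Severity tiers are consolidated per track after base-class correction: the
modal tier among raw tiered frames inside the phenotype segment wins, ties
resolving toward the more severe tier.

A "no unknown" mode (used for species imaged from stages where phenotypes
are already distinguishable, e.g. medaka) pins t1 = 0 so the phenotype
segment starts at the first frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .taxonomy import ClassTaxonomy, SEVERITY_TIERS

__all__ = [
    "TrackClassification", "correct_track", "brute_force_oracle",
    "correct_severity", "correct_plate", "is_valid_transition_sequence",
    "candidate_key", "candidate_sequence",
]

_NO_TRANSITION = 10**9  # stands in for "no transition" (latest possible)


@dataclass
class TrackClassification:
    """Raw vs corrected label path of one track plus the final call."""

    raw_labels: list[str]  # as provided (may carry severity tiers)
    corrected_labels: list[str]  # base-class, piecewise constant
    transition_frames: list[int]  # sequence positions where the label changes
    final_class: str
    severity: str | None
    cost: int | float
    track_id: int | None = None
    t1: int = 0  # phenotype-segment start (search parametrization)
    t2: int = 0  # dead-segment start


def candidate_sequence(T: int, t1: int, t2: int, x: str | None) -> list[str]:
    """Corrected sequence for change points (t1, t2) and phenotype x."""
    return ["unknown"] * t1 + [x] * (t2 - t1) + ["dead"] * (T - t2)


def _candidate_structure(T: int, t1: int, t2: int):
    """(n_transitions, first_transition_frame) of a candidate."""
    seg_bounds = []
    if t1 > 0:
        seg_bounds.append(t1)  # unknown -> next
    if t2 > t1 and t2 < T:
        seg_bounds.append(t2)  # phenotype -> dead
    if t1 == t2 and 0 < t1 < T:
        seg_bounds = [t1]  # unknown -> dead directly
    bounds = sorted(set(b for b in seg_bounds if 0 < b < T))
    n_trans = len(bounds)
    first = bounds[0] if bounds else _NO_TRANSITION
    return n_trans, first


def candidate_key(cost, T: int, t1: int, t2: int, x_rank: int):
    """Total order used to pick among equal-cost candidates (minimized).

    Keys: cost, fewer transitions, later first transition, taxonomy order
    of the phenotype class, then larger t1 and t2 for determinism.
    """
    n_trans, first = _candidate_structure(T, t1, t2)
    rank = x_rank if t2 > t1 else -1  # phenotype segment empty: x irrelevant
    return (cost, n_trans, -first, rank, -t1, -t2)


def _base_labels(raw: Sequence[str], taxonomy: ClassTaxonomy) -> list[str]:
    return [taxonomy.base_of(l) for l in raw]


def _prefix_counts(base: list[str], label: str) -> np.ndarray:
    arr = np.fromiter((l == label for l in base), dtype=float, count=len(base))
    out = np.zeros(len(base) + 1)
    np.cumsum(arr, out=out[1:])
    return out


def correct_track(raw_labels: Sequence[str],
                  taxonomy: ClassTaxonomy | None = None,
                  no_unknown: bool = False,
                  probs: np.ndarray | None = None,
                  labels_order: Sequence[str] | None = None,
                  track_id: int | None = None) -> TrackClassification:
    """Least-cost valid piecewise-constant correction of one track.

    By default the cost of a candidate is the number of frames whose raw
    argmax label disagrees with it.  When ``probs`` (shape (T, n_labels),
    with ``labels_order``) is given, a probabilistic cost
    sum_t (1 - p_t(candidate_t)) is used instead.
    """
    taxonomy = taxonomy or ClassTaxonomy()
    T = len(raw_labels)
    if T < 1:
        raise ValueError("track must have at least one frame")
    base = _base_labels(list(raw_labels), taxonomy)  # raises on bad labels

    phen = list(taxonomy.phenotype_classes)
    if probs is not None:
        probs = np.asarray(probs, dtype=float)
        if labels_order is None or probs.shape != (T, len(labels_order)):
            raise ValueError("probs requires labels_order of matching shape")
        # collapse tiered columns onto base classes
        base_cols = {c: np.zeros(T) for c in taxonomy.base_classes}
        for j, lab in enumerate(labels_order):
            base_cols[taxonomy.base_of(lab)] += probs[:, j]
        def prefix(label):
            out = np.zeros(T + 1)
            np.cumsum(base_cols[label], out=out[1:])
            return out
    else:
        def prefix(label):
            return _prefix_counts(base, label)

    U = prefix("unknown")
    D = prefix("dead")
    d_total = D[T]

    best_key = None
    best = None  # (t1, t2, x)
    for x_rank, x in enumerate(phen):
        Xc = prefix(x)
        a = U - Xc  # a[t1]: saved frames in [0, t1) if labelled unknown
        b = Xc - D  # b[t2] + d_total: saved in [t1, t2) + [t2, T)
        if no_unknown:
            arg_late = np.zeros(T + 1, dtype=int)  # t1 pinned at 0
        else:
            # running argmax of a with late (larger index) preference
            arg_late = np.empty(T + 1, dtype=int)
            arg_late[0] = 0
            for t in range(1, T + 1):
                arg_late[t] = t if a[t] >= a[arg_late[t - 1]] else arg_late[t - 1]
        for t2 in range(T + 1):
            m = a[arg_late[t2]]
            saved = b[t2] + m + d_total
            cost = T - saved
            t1_candidates = {arg_late[t2]}
            if not no_unknown:
                if t2 > 0 and a[arg_late[t2 - 1]] == m:
                    t1_candidates.add(arg_late[t2 - 1])
                if a[0] == m:
                    t1_candidates.add(0)
                if a[t2] == m:
                    t1_candidates.add(t2)
            for t1 in t1_candidates:
                key = candidate_key(cost, T, t1, t2, x_rank)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (t1, t2, x)

    t1, t2, x = best
    corrected = candidate_sequence(T, t1, t2, x)
    n_trans, first = _candidate_structure(T, t1, t2)
    transitions = []
    for t in range(1, T):
        if corrected[t] != corrected[t - 1]:
            transitions.append(t)
    final = x if t2 > t1 else ("dead" if t2 < T else "unknown")
    cost_out = sum(c != b for c, b in zip(corrected, base))
    if probs is not None:
        cost_out = float(best_key[0])

    severity = None
    if final in taxonomy.tiered_classes:
        severity = correct_severity(corrected, list(raw_labels), taxonomy,
                                    final_class=final, warn=False)
    return TrackClassification(
        raw_labels=list(raw_labels), corrected_labels=corrected,
        transition_frames=transitions, final_class=final, severity=severity,
        cost=cost_out, track_id=track_id, t1=t1, t2=t2)


def brute_force_oracle(raw_labels: Sequence[str],
                       taxonomy: ClassTaxonomy | None = None,
                       no_unknown: bool = False):
    """Exhaustive search over every valid candidate; returns
    ``(min_cost, argmin)`` where argmin is the list of all (t1, t2, x)
    achieving the minimum.  O(T^2 x C); the independent check for
    :func:`correct_track`."""
    taxonomy = taxonomy or ClassTaxonomy()
    T = len(raw_labels)
    base = _base_labels(list(raw_labels), taxonomy)
    phen = list(taxonomy.phenotype_classes)
    U = _prefix_counts(base, "unknown")
    D = _prefix_counts(base, "dead")
    min_cost = None
    argmin: list[tuple[int, int, str]] = []
    valid = np.triu(np.ones((T + 1, T + 1), dtype=bool))  # t1 <= t2
    if no_unknown:
        valid &= (np.arange(T + 1) == 0)[:, None]
    for x in phen:
        Xc = _prefix_counts(base, x)
        agree = (U - Xc)[:, None] + (Xc - D)[None, :] + D[T]
        cost = np.where(valid, T - agree, np.inf)
        c = int(cost.min())
        if min_cost is None or c < min_cost:
            min_cost = c
            argmin = []
        if c == min_cost:
            for t1, t2 in np.argwhere(cost == c):
                argmin.append((int(t1), int(t2), x))
    return min_cost, argmin


def is_valid_transition_sequence(labels: Sequence[str],
                                 taxonomy: ClassTaxonomy | None = None) -> bool:
    """True iff the sequence follows unknown -> one phenotype -> dead
    (each segment optional, no label revisited)."""
    taxonomy = taxonomy or ClassTaxonomy()
    segs: list[str] = []
    for lab in labels:
        if not segs or segs[-1] != lab:
            segs.append(lab)
    if len(set(segs)) != len(segs):
        return False  # a label repeats in non-adjacent segments
    stage = 0  # 0: unknown allowed, 1: phenotype, 2: dead
    for lab in segs:
        if lab == "unknown":
            if stage > 0:
                return False
            stage = 1
        elif lab in taxonomy.phenotype_classes:
            if stage > 1 or any(s in taxonomy.phenotype_classes for s in segs[: segs.index(lab)]):
                return False
            stage = 2
        elif lab == "dead":
            stage = 3
        else:
            return False
    return True


def correct_severity(corrected_labels: Sequence[str],
                     raw_labels: Sequence[str],
                     taxonomy: ClassTaxonomy | None = None,
                     final_class: str | None = None,
                     warn: bool = True) -> str | None:
    """Modal severity tier over the phenotype segment; ties go severe.

    Looks at frames where the corrected label equals the final (tiered) base
    class and the raw label carries a tier of that class.  Returns None with
    a warning when no tiered frames exist.
    """
    taxonomy = taxonomy or ClassTaxonomy()
    if final_class is None:
        phen = [l for l in corrected_labels
                if l in taxonomy.phenotype_classes]
        final_class = phen[-1] if phen else None
    if final_class not in taxonomy.tiered_classes:
        return None
    counts = {t: 0 for t in taxonomy.tiers}
    for corr, raw in zip(corrected_labels, raw_labels):
        if corr != final_class:
            continue
        try:
            if taxonomy.base_of(raw) != final_class:
                continue
        except ValueError:
            continue
        tier = taxonomy.tier_of(raw)
        if tier is not None:
            counts[tier] += 1
    if not any(counts.values()):
        if warn:
            warnings.warn(
                f"no tiered frames for final class {final_class!r}; "
                "severity left unset", stacklevel=2)
        return None
    best = max(counts.values())
    # ties resolve toward the more severe tier
    for tier in reversed(taxonomy.tiers):
        if counts[tier] == best:
            return tier
    return None


def correct_plate(track_predictions, taxonomy: ClassTaxonomy | None = None,
                  no_unknown: bool = False):
    """Apply track correction + severity consolidation to every track.

    ``track_predictions`` is an iterable of objects with ``track_id``,
    ``frames`` and ``labels`` attributes (e.g.
    :class:`~embryoscreen.classifier.TrackPrediction`) or of
    ``(track_id, labels)`` pairs.  Returns the corrected tracks and a
    per-track summary DataFrame (track_id, final_class, severity,
    t_transition1, t_transition2, cost).
    """
    taxonomy = taxonomy or ClassTaxonomy()
    results: list[TrackClassification] = []
    rows = []
    for tp in track_predictions:
        if hasattr(tp, "labels"):
            track_id, labels, frames = tp.track_id, tp.labels, list(tp.frames)
        else:
            track_id, labels = tp
            frames = list(range(len(labels)))
        if not labels:
            continue
        tc = correct_track(labels, taxonomy, no_unknown=no_unknown,
                           track_id=track_id)
        results.append(tc)
        t1f = frames[tc.t1] if 0 < tc.t1 < len(frames) else (
            frames[0] if tc.t1 == 0 else None)
        t2f = frames[tc.t2] if tc.t2 < len(frames) else None
        rows.append({"track_id": track_id, "final_class": tc.final_class,
                     "severity": tc.severity,
                     "t_transition1": t1f if tc.t1 > 0 else None,
                     "t_transition2": t2f if tc.t2 < len(labels) else None,
                     "cost": tc.cost})
    df = pd.DataFrame(rows, columns=["track_id", "final_class", "severity",
                                     "t_transition1", "t_transition2", "cost"])
    return results, df
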