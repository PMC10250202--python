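"""Phenotype class vocabulary, severity tiers and developmental-time conventions.

The classification target is a discrete phenotype per embryo image: ``unknown``
(too early to tell), ``normal``, one of seven signalling-pathway defect classes
(loss of BMP, Wnt, FGF, Shh, PCP or Nodal activity, or gain of retinoic-acid
signalling), or ``dead``.  The BMP and Nodal loss-of-function classes carry
severity tiers (weak / intermediate / severe, roughly 30 / 60 / 100 % phenotype
penetrance), giving 14 flat labels by default.  A special label ``cut`` marks
partially visible embryos; it is excluded from training and metrics.

Developmental time is expressed in hours post-fertilization (h.p.f.) and mapped
linearly onto [0, 1] between configurable anchors (defaults 2 and 26 h.p.f.)
to form the timestamp input of the classifier.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "CUT_LABEL",
    "SEVERITY_TIERS",
    "TIER_PERCENT",
    "ClassTaxonomy",
    "TimeMapping",
    "normalize_time",
    "shift_annotations_earlier",
]

#: Label for partially visible embryos; never trained on, never predicted.
CUT_LABEL = "cut"

#: Severity tiers ordered from least to most severe.
SEVERITY_TIERS = ("weak", "intermediate", "severe")

#: Approximate phenotype penetrance attached to each tier, in percent.
TIER_PERCENT = {"weak": 30, "intermediate": 60, "severe": 100}

# Canonical machine names; display aliases are used only in reports.
_DEFAULT_BASE_CLASSES = (
    "unknown",
    "normal",
    "dead",
    "bmp_lof",
    "nodal_lof",
    "ra_gain",
    "wnt_lof",
    "fgf_lof",
    "shh_lof",
    "pcp_lof",
)

_DEFAULT_TIERED = ("bmp_lof", "nodal_lof")

_DISPLAY_ALIASES = {
    "unknown": "Unknown",
    "normal": "Normal",
    "dead": "Dead",
    "bmp_lof": "-BMP",
    "nodal_lof": "-Nodal",
    "ra_gain": "+RA",
    "wnt_lof": "-Wnt",
    "fgf_lof": "-FGF",
    "shh_lof": "-Shh",
    "pcp_lof": "-PCP",
}


@dataclass(frozen=True)
class ClassTaxonomy:
    """The phenotype vocabulary shared by classifier, transition logic and reports.

    Parameters
    ----------
    base_classes
        Ordered base-class names.  The order is normative: it fixes the flat
        label order, argmax tie-breaking and transition-logic tie-breaking.
    tiered_classes
        Subset of ``base_classes`` that carries severity tiers.
    tiers
        Tier names ordered from least to most severe.
    """

    base_classes: tuple[str, ...] = _DEFAULT_BASE_CLASSES
    tiered_classes: tuple[str, ...] = _DEFAULT_TIERED
    tiers: tuple[str, ...] = SEVERITY_TIERS
    tier_percent: dict = field(default_factory=lambda: dict(TIER_PERCENT))

    def __post_init__(self) -> None:
        for c in self.tiered_classes:
            if c not in self.base_classes:
                raise ValueError(f"tiered class {c!r} not among base classes")
        if len(set(self.base_classes)) != len(self.base_classes):
            raise ValueError("duplicate base class names")

    # -- flat labels ----------------------------------------------------
    def flatten_labels(self) -> list[str]:
        """Return the ordered flat label list (default: 14 labels).

        Untiered base classes contribute themselves; each tiered class
        contributes one ``<base>_<tier>`` label per tier, in tier order,
        at the position of the base class.
        """
        labels: list[str] = []
        for c in self.base_classes:
            if c in self.tiered_classes:
                labels.extend(f"{c}_{t}" for t in self.tiers)
            else:
                labels.append(c)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate flat labels")
        return labels

    def base_of(self, flat_label: str) -> str:
        """Collapse a flat label to its base class (identity for untiered)."""
        if flat_label in self.base_classes:
            return flat_label
        for c in self.tiered_classes:
            for t in self.tiers:
                if flat_label == f"{c}_{t}":
                    return c
        raise ValueError(f"label {flat_label!r} not in taxonomy")

    def tier_of(self, flat_label: str) -> str | None:
        """Return the severity tier of a flat label, or None if untiered."""
        if flat_label in self.base_classes:
            return None
        base = self.base_of(flat_label)
        return flat_label[len(base) + 1 :]

    def is_valid_label(self, label: str) -> bool:
        try:
            self.base_of(label)
            return True
        except ValueError:
            return label == CUT_LABEL

    @property
    def phenotype_classes(self) -> tuple[str, ...]:
        """Base classes an embryo can transition to from unknown (incl. normal)."""
        return tuple(
            c for c in self.base_classes if c not in ("unknown", "dead")
        )

    def display_name(self, label: str) -> str:
        try:
            base = self.base_of(label)
        except ValueError:
            return label
        tier = self.tier_of(label)
        name = _DISPLAY_ALIASES.get(base, base)
        return f"{name} ({tier})" if tier else name

    @classmethod
    def from_config(cls, section: dict | None) -> "ClassTaxonomy":
        """Build a taxonomy from the ``taxonomy`` section of a YAML config."""
        if not section:
            return cls()
        return cls(
            base_classes=tuple(section.get("base_classes", _DEFAULT_BASE_CLASSES)),
            tiered_classes=tuple(section.get("tiered_classes", _DEFAULT_TIERED)),
            tiers=tuple(section.get("tiers", SEVERITY_TIERS)),
        )


@dataclass(frozen=True)
class TimeMapping:
    """Linear map from developmental time (h.p.f.) to the unit interval.

    tau(t) = clamp((t - t0) / (t1 - t0), 0, 1); defaults anchor 0 at ~2 h.p.f.
    and 1 at ~26 h.p.f., the span of the first day of development covered by
    a 720-frame, 120-s-interval acquisition.
    """

    t0_hpf: float = 2.0
    t1_hpf: float = 26.0

    def __post_init__(self) -> None:
        if not self.t1_hpf > self.t0_hpf:
            raise ValueError("TimeMapping requires t1_hpf > t0_hpf")

    def __call__(self, t_hpf: float) -> float:
        return normalize_time(t_hpf, self)


def normalize_time(t_hpf, mapping: TimeMapping | None = None):
    """Map developmental time in h.p.f. to tau in [0, 1], clamped outside."""
    import numpy as np

    if mapping is None:
        mapping = TimeMapping()
    tau = (np.asarray(t_hpf, dtype=float) - mapping.t0_hpf) / (
        mapping.t1_hpf - mapping.t0_hpf
    )
    tau = np.clip(tau, 0.0, 1.0)
    return float(tau) if np.ndim(t_hpf) == 0 else tau


def shift_annotations_earlier(records: Sequence, n_frames: int) -> list:
    """Move each track's phenotype onset ``n_frames`` earlier (floored at 0).

    For every track, the first frame of each non-unknown phenotype label is
    shifted earlier by ``n_frames``: frames within the shift window that were
    labelled ``unknown`` adopt the phenotype label.  ``dead`` and ``cut``
    labels are left untouched, as are label identities elsewhere.  This is
    the retraining trick that teaches the classifier to call phenotypes
    before they are recognisable by eye.

    Parameters
    ----------
    records
        Per-frame :class:`~embryoscreen.io.AnnotationRecord` list for one well,
        ordered by frame.  Embryos are grouped by ``track_id`` (entries with
        no track are left unchanged).
    n_frames
        Non-negative shift in frames.
    """
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    records = [copy.deepcopy(r) for r in records]
    if n_frames == 0:
        return records

    # Group entries by track across frames, keeping per-frame order.
    by_track: dict[int, list] = {}
    for rec in records:
        for emb in rec.embryos:
            if emb.track_id is not None:
                by_track.setdefault(emb.track_id, []).append(emb)

    for entries in by_track.values():
        labels = [e.class_label for e in entries]
        # Find onsets: first index of each contiguous run of a shiftable label.
        for i, lab in enumerate(labels):
            if lab in (None, "unknown", "dead", CUT_LABEL):
                continue
            if i > 0 and labels[i - 1] == lab:
                continue  # not an onset
            start = max(0, i - n_frames)
            for j in range(start, i):
                if entries[j].class_label == "unknown":
                    entries[j].class_label = lab
                    entries[j].severity = entries[i].severity
    return records
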