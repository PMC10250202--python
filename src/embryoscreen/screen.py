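"""Plate-screen aggregation: per-well class counts and majority phenotype.

Each well of a drug screen accumulates one classified label per embryo per
frame over the whole time series.  The well's call is the majority
phenotype: the class to which the highest number of embryo images was
assigned.  On a tie the well is flagged and the documented priority is
applied: dead beats any phenotype (a well full of dying embryos is a
viability modulator), phenotype classes beat normal in taxonomy order, and
unknown loses to everything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .taxonomy import ClassTaxonomy

__all__ = ["WellSummary", "summarize_well", "summarize_plate"]


@dataclass
class WellSummary:
    """Per-class image counts of one well and its majority call."""

    plate_id: str
    well_id: str
    counts: dict[str, int]
    majority_class: str
    tie: bool
    treatment: str | None = None

    @property
    def n_images(self) -> int:
        return sum(self.counts.values())


def _tie_priority(taxonomy: ClassTaxonomy) -> list[str]:
    # dead > phenotype classes (taxonomy order, excluding normal) > normal > unknown
    phen = [c for c in taxonomy.phenotype_classes if c != "normal"]
    return ["dead"] + phen + ["normal", "unknown"]


def summarize_well(labels: Iterable[str], taxonomy: ClassTaxonomy | None = None,
                   plate_id: str = "", well_id: str = "",
                   collapse_severity: bool = True,
                   from_frame_labels: Sequence[tuple[int, str]] | None = None,
                   from_frame: int = 0) -> WellSummary:
    """Count classified embryo-images per class and call the majority.

    ``labels`` are the corrected per-image labels of the well over the full
    time series.  Severity tiers are collapsed to their base class by
    default.  Alternatively pass ``from_frame_labels`` as (frame_index,
    label) pairs together with ``from_frame`` to exclude early frames from
    the vote.
    """
    taxonomy = taxonomy or ClassTaxonomy()
    if from_frame_labels is not None:
        labels = [l for f, l in from_frame_labels if f >= from_frame]
    labels = list(labels)
    counts: dict[str, int] = {c: 0 for c in taxonomy.base_classes} \
        if collapse_severity else {}
    for lab in labels:
        key = taxonomy.base_of(lab) if collapse_severity else lab
        counts[key] = counts.get(key, 0) + 1
    if not labels:
        return WellSummary(plate_id, well_id, counts, "unknown", tie=False)
    top = max(counts.values())
    leaders = sorted(c for c, n in counts.items() if n == top)
    tie = len(leaders) > 1
    if tie:
        priority = _tie_priority(taxonomy)
        ranked = [c for c in priority if c in leaders]
        majority = ranked[0] if ranked else leaders[0]
    else:
        majority = leaders[0]
    return WellSummary(plate_id, well_id, counts, majority, tie)


def summarize_plate(well_summaries: Sequence[WellSummary],
                    layout: pd.DataFrame | None = None,
                    timecourse_labels: Mapping[str, Sequence[tuple[int, str]]] | None = None,
                    taxonomy: ClassTaxonomy | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the plate report (one row per well) and a long-format timecourse.

    ``layout`` has columns plate_id, well_id, treatment (and optionally
    concentration, units); a well missing from the layout is reported with
    treatment "unmapped" and a warning.  ``timecourse_labels`` optionally
    maps well_id -> (frame_index, label) pairs for the per-frame CSV.
    The report is order-invariant: rows are sorted by (plate_id, well_id).
    """
    taxonomy = taxonomy or ClassTaxonomy()
    classes = list(taxonomy.base_classes)
    mapping: dict[tuple[str, str], dict] = {}
    if layout is not None:
        for _, row in layout.iterrows():
            mapping[(str(row.get("plate_id", "")), str(row["well_id"]))] = \
                row.to_dict()

    rows = []
    for ws in well_summaries:
        meta = mapping.get((ws.plate_id, ws.well_id))
        if meta is None and layout is not None:
            warnings.warn(
                f"well {ws.well_id} (plate {ws.plate_id!r}) absent from "
                "layout; treatment set to 'unmapped'", stacklevel=2)
        treatment = (meta or {}).get("treatment", "unmapped"
                                     if layout is not None else None)
        row = {"plate_id": ws.plate_id, "well_id": ws.well_id,
               "treatment": treatment,
               "concentration": (meta or {}).get("concentration"),
               "units": (meta or {}).get("units"),
               "majority_class": ws.majority_class, "tie": ws.tie,
               "n_images": ws.n_images}
        for c in classes:
            row[f"count_{c}"] = ws.counts.get(c, 0)
        rows.append(row)
    report = pd.DataFrame(rows).sort_values(
        ["plate_id", "well_id"]).reset_index(drop=True)

    tc_rows = []
    if timecourse_labels:
        for well_id in sorted(timecourse_labels):
            per_frame: dict[tuple[int, str], int] = {}
            for frame, lab in timecourse_labels[well_id]:
                base = taxonomy.base_of(lab)
                per_frame[(frame, base)] = per_frame.get((frame, base), 0) + 1
            for (frame, base), n in sorted(per_frame.items()):
                tc_rows.append({"well_id": well_id, "frame_index": frame,
                                "class": base, "count": n})
    timecourse = pd.DataFrame(
        tc_rows, columns=["well_id", "frame_index", "class", "count"])
    return report, timecourse
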