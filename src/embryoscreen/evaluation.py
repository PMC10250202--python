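"""Classification metrics, baselines and the end-to-end evaluation harness.

Subset accuracy is the fraction of images whose predicted label equals the
true label exactly.  Per-class precision, recall and F-score use one-vs-rest
counts; F = 2PR/(P+R), defined as 0 when P+R = 0.  Displayed confusion
matrices exclude the ``unknown`` class (early frames would otherwise
dominate them) while the overall accuracy and F-scores include it; both
variants are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs

from .taxonomy import ClassTaxonomy, TimeMapping

__all__ = ["MetricsReport", "compute_metrics", "random_guess_baseline",
           "evaluate_pipeline"]


@dataclass
class MetricsReport:
    """Subset accuracy, per-class P/R/F, macro F and confusion matrices."""

    accuracy: float
    per_class: pd.DataFrame  # index: class; columns: precision/recall/f_score/support
    macro_f: float
    confusion: pd.DataFrame  # all classes, rows = truth
    confusion_display: pd.DataFrame  # unknown excluded
    n: int


def compute_metrics(true_labels: Sequence[str], predicted_labels: Sequence[str],
                    taxonomy: ClassTaxonomy | None = None,
                    labels_order: Sequence[str] | None = None) -> MetricsReport:
    """Metrics for equal-length truth/prediction label vectors."""
    if len(true_labels) == 0 or len(true_labels) != len(predicted_labels):
        raise ValueError("need equal-length, non-empty label vectors")
    taxonomy = taxonomy or ClassTaxonomy()
    if labels_order is None:
        flat = taxonomy.flatten_labels()
        present = set(true_labels) | set(predicted_labels)
        labels_order = [l for l in flat if l in present]
        labels_order += sorted(present - set(labels_order))
    y_t = list(true_labels)
    y_p = list(predicted_labels)

    accuracy = float(np.mean([t == p for t, p in zip(y_t, y_p)]))
    prec, rec, f, support = _sk_prfs(y_t, y_p, labels=labels_order,
                                     zero_division=0)
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f_score": f, "support": support},
        index=pd.Index(labels_order, name="class"))
    in_truth = [l for l in labels_order if l in set(y_t)]
    macro_f = float(per_class.loc[in_truth, "f_score"].mean()) if in_truth else 0.0

    cm = _sk_confusion(y_t, y_p, labels=labels_order)
    confusion = pd.DataFrame(cm, index=pd.Index(labels_order, name="true"),
                             columns=pd.Index(labels_order, name="predicted"))
    disp = [l for l in labels_order if l != "unknown"]
    confusion_display = confusion.loc[disp, disp]
    return MetricsReport(accuracy, per_class, macro_f, confusion,
                         confusion_display, len(y_t))


def random_guess_baseline(n_images: int, n_classes: int,
                          n_replicates: int = 10_000,
                          seed: int = 0) -> tuple[float, float]:
    """Mean +- sd subset accuracy of uniform random label assignment.

    Each replicate assigns labels drawn uniformly from ``n_classes``
    candidates to ``n_images`` images with a fixed true labeling; the mean
    converges to 1/n_classes regardless of the truth distribution.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = np.random.default_rng(seed)
    truth = rng.integers(0, n_classes, size=n_images)  # arbitrary, fixed
    guesses = rng.integers(0, n_classes, size=(n_replicates, n_images))
    acc = (guesses == truth[None, :]).mean(axis=1)
    return float(acc.mean()), float(acc.std())


def evaluate_pipeline(model, phantom_result, labels_order: Sequence[str],
                      detection_config, tracking_config=None,
                      taxonomy: ClassTaxonomy | None = None,
                      time_mapping: TimeMapping | None = None,
                      pad_margin_frac: float = 0.25):
    """Run detect -> track -> classify -> correct on phantom plates and score
    both stages against ground truth.

    Returns a dict with per-frame MetricsReports before ("raw") and after
    ("corrected") transition correction, the per-track final-class accuracy,
    and the matched track count.  Tracks are matched to ground-truth
    identities by nearest center per frame.
    """
    from .classifier import classify_track
    from .detection import detect_embryos
    from .tracking import TrackingConfig, link_tracks
    from .trajectory import correct_track

    taxonomy = taxonomy or ClassTaxonomy()
    tracking_config = tracking_config or TrackingConfig()
    y_raw_t, y_raw_p = [], []
    y_cor_t, y_cor_p = [], []
    final_hits, n_tracks = 0, 0

    for well, frames in phantom_result.frames.items():
        records = phantom_result.annotations[well]
        truth_by_frame = {rec.frame_index: rec for rec in records}
        per_frame = {fr.frame_index: detect_embryos(fr, detection_config)
                     for fr in frames}
        tracks = link_tracks(per_frame, tracking_config)
        frame_map = {fr.frame_index: fr for fr in frames}
        scheds = phantom_result.schedules[well]

        for track in tracks:
            pred = classify_track(model, track, frame_map, time_mapping,
                                  labels_order, pad_margin_frac)
            if not pred.labels:
                continue
            # ground-truth identity: nearest annotated center, majority vote
            gt_ids = []
            for (fi, det) in track.detections:
                rec = truth_by_frame.get(fi)
                if rec is None or not rec.embryos:
                    gt_ids.append(None)
                    continue
                d = [np.hypot(det.center_x_px - e.center_x_px,
                              det.center_y_px - e.center_y_px)
                     for e in rec.embryos]
                gt_ids.append(rec.embryos[int(np.argmin(d))].track_id)
            ids = [g for g in gt_ids if g is not None]
            if not ids:
                continue
            gt_id = max(set(ids), key=ids.count)
            sched = scheds[gt_id]
            truth_labels = [sched.label_at(fi, taxonomy)
                            for fi in pred.frames]
            truth_base = [taxonomy.base_of(l) for l in truth_labels]
            raw_base = [taxonomy.base_of(l) for l in pred.labels]
            tc = correct_track(pred.labels, taxonomy, track_id=track.track_id)
            y_raw_t += truth_base
            y_raw_p += raw_base
            y_cor_t += truth_base
            y_cor_p += tc.corrected_labels
            truth_final = taxonomy.base_of(
                sched.label_at(pred.frames[-1], taxonomy))
            final_hits += int(tc.final_class == truth_final)
            n_tracks += 1

    report_raw = compute_metrics(y_raw_t, y_raw_p, taxonomy) if y_raw_t else None
    report_cor = compute_metrics(y_cor_t, y_cor_p, taxonomy) if y_cor_t else None
    return {
        "raw": report_raw,
        "corrected": report_cor,
        "per_track_final_accuracy": final_hits / n_tracks if n_tracks else 0.0,
        "n_tracks": n_tracks,
    }
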