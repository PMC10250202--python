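"""Embryo detection: circular Hough transform within a configured radius range.

Fish embryos in their chorion appear as near-circular disks in bright-field
well images, so a circle detector with a per-experiment radius range is
sufficient (and is pluggable: see :class:`EmbryoDetector` for the interface
a replacement detector for non-spherical species must satisfy).

The pipeline is: Canny edges on the unit-range grayscale frame, a circular
Hough accumulator over the radius range (2-px radius steps), candidate peaks
above a normalized accumulator threshold, and greedy non-maximum suppression
by a minimum center distance with the highest score winning.  Scores are the
accumulator value normalized by its theoretical maximum for that radius, so
they are comparable across radii and lie in [0, 1].  Edge detection operates
on gradients, so the output is invariant to adding a constant intensity
offset to the frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from skimage.feature import canny
from skimage.transform import hough_circle, resize

from .io import PlateFrame

__all__ = ["Detection", "DetectionConfig", "EmbryoDetector",
           "HoughEmbryoDetector", "detect_embryos", "crop_embryo"]


@dataclass(frozen=True)
class Detection:
    """A circle hypothesis in one frame; score in [0, 1]."""

    frame_index: int
    center_x_px: float
    center_y_px: float
    radius_px: float
    score: float


@dataclass(frozen=True)
class DetectionConfig:
    """Hough detector parameters.

    r_min / r_max bound the embryo radius in pixels (set per experiment from
    the acquisition optics); radius_step is the accumulator's radius grid
    spacing; accumulator_threshold is on the normalized [0, 1] score;
    min_center_dist suppresses duplicate circles (defaults to r_min).
    """

    r_min: float
    r_max: float
    radius_step: float = 2.0
    canny_sigma: float = 2.0
    accumulator_threshold: float = 0.30
    min_center_dist: float | None = None

    def __post_init__(self) -> None:
        if self.r_min <= 0 or self.r_min > self.r_max:
            raise ValueError("detection config requires 0 < r_min <= r_max")
        if self.radius_step <= 0:
            raise ValueError("radius_step must be positive")

    @property
    def effective_min_center_dist(self) -> float:
        return self.min_center_dist if self.min_center_dist is not None else self.r_min

    @classmethod
    def from_config(cls, section: dict) -> "DetectionConfig":
        return cls(
            r_min=float(section["r_min"]),
            r_max=float(section["r_max"]),
            radius_step=float(section.get("radius_step", 2.0)),
            canny_sigma=float(section.get("canny_sigma", 2.0)),
            accumulator_threshold=float(section.get("accumulator_threshold", 0.30)),
            min_center_dist=section.get("min_center_dist"),
        )


class EmbryoDetector(Protocol):
    """Interface a pluggable detector must satisfy."""

    def __call__(self, frame: PlateFrame | np.ndarray) -> list[Detection]: ...


def _as_float_gray(frame: PlateFrame | np.ndarray) -> tuple[np.ndarray, int]:
    if isinstance(frame, PlateFrame):
        img = frame.to_float()
        idx = frame.frame_index
    else:
        img = np.asarray(frame, dtype=float)
        idx = 0
    if img.ndim == 3:
        img = img.mean(axis=2)
    return img, idx


class HoughEmbryoDetector:
    """Circular-Hough detector configured by :class:`DetectionConfig`."""

    def __init__(self, config: DetectionConfig):
        self.config = config

    def __call__(self, frame: PlateFrame | np.ndarray) -> list[Detection]:
        cfg = self.config
        img, frame_index = _as_float_gray(frame)
        edges = canny(img, sigma=cfg.canny_sigma)
        if not edges.any():
            return []
        radii = np.arange(cfg.r_min, cfg.r_max + 1e-9, cfg.radius_step)
        # normalize_by_circumference scales each plane by full-circle support,
        # giving the score its theoretical [0, 1] range per radius
        acc = hough_circle(edges, radii, normalize=True, full_output=False)

        candidates: list[tuple[float, float, float, float]] = []
        for plane, r in zip(acc, radii):
            thr = cfg.accumulator_threshold
            ys, xs = np.nonzero(plane > thr)
            for y, x in zip(ys, xs):
                candidates.append((float(plane[y, x]), float(y), float(x), float(r)))
        if not candidates:
            return []
        # highest score first; deterministic tie-break by (y, x) ascending
        candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
        kept: list[Detection] = []
        min_d = cfg.effective_min_center_dist
        for score, y, x, r in candidates:
            if all(np.hypot(x - k.center_x_px, y - k.center_y_px) >= min_d
                   for k in kept):
                kept.append(Detection(frame_index, x, y, r, min(score, 1.0)))
        kept.sort(key=lambda d: (-d.score, d.center_y_px, d.center_x_px))
        return kept


def detect_embryos(frame: PlateFrame | np.ndarray,
                   config: DetectionConfig) -> list[Detection]:
    """Detect embryos in one frame (see module docstring for the algorithm)."""
    return HoughEmbryoDetector(config)(frame)


def crop_embryo(frame: PlateFrame | np.ndarray, detection: Detection,
                out_size_px: int = 224, pad_margin_frac: float = 0.25) -> np.ndarray:
    """Square crop around a detection, resampled to ``out_size_px``.

    The crop side is 2 * radius * (1 + pad_margin_frac); regions outside the
    frame are padded with the frame's median intensity.  Returns a unit-range
    float array of shape (out_size_px, out_size_px).
    """
    if out_size_px < 8:
        raise ValueError("out_size_px must be >= 8")
    img, _ = _as_float_gray(frame)
    side = 2.0 * detection.radius_px * (1.0 + pad_margin_frac)
    n = max(8, int(round(side)))
    median = float(np.median(img))
    x0 = int(round(detection.center_x_px - side / 2.0))
    y0 = int(round(detection.center_y_px - side / 2.0))
    patch = np.full((n, n), median)
    sy0, sy1 = max(0, y0), min(img.shape[0], y0 + n)
    sx0, sx1 = max(0, x0), min(img.shape[1], x0 + n)
    if sy1 > sy0 and sx1 > sx0:
        patch[sy0 - y0: sy1 - y0, sx0 - x0: sx1 - x0] = img[sy0:sy1, sx0:sx1]
    if n == out_size_px:
        return patch
    return resize(patch, (out_size_px, out_size_px), order=1,
                  anti_aliasing=n > out_size_px, mode="edge")
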