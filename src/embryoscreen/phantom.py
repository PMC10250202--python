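"""Seeded synthetic well time-lapses with known ground truth.

The phantom emulates the acquisition regime of a well-plate bright-field
screen: one image per well per timepoint (defaults: 720 frames at 120-s
intervals, i.e. a 24-h window), several non-overlapping disk-shaped embryos
per well, slow random-walk drift, and sensor noise (Gaussian plus
salt-and-pepper).  Each embryo follows a class schedule: its interior is
class-neutral before a per-embryo onset frame, carries a class-specific
geometric motif from the onset on (amplitude scaled by severity tier), and
collapses to a low-contrast speckle from an optional death frame on.

Motifs are geometric/textural stand-ins, not biological mimicry: they make
detection, classification and track correction testable with exactly known
ground truth.  By construction the motifs are separable at full contrast: a
template-correlation oracle classifier reaches 100 % on noise-free renders
after onset (see :func:`oracle_classify`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AnnotationRecord, EmbryoAnnotation, PlateFrame, frame_filename, write_annotation_dir, write_image
from .taxonomy import ClassTaxonomy, SEVERITY_TIERS

__all__ = [
    "EmbryoSchedule",
    "PhantomSpec",
    "PhantomResult",
    "generate_phantom",
    "corrupt_labels",
    "render_motif",
    "oracle_classify",
    "generate_training_crops",
]

# interior / background / rim intensities on the unit scale
_BG = 0.62
_INTERIOR = 0.45
_RIM = 0.22
_RIM_WIDTH = 3.0
_MOTIF_AMP = 0.30

_SEVERITY_SCALE = {"weak": 0.30, "intermediate": 0.60, "severe": 1.00, None: 1.00}

#: default mapping base class -> motif name.  Every default motif is
#: distinguishable from the others by rotation/mirror-invariant structure
#: (spot count, ring count, radial profile), mirroring the orientation
#: invariance of real phenotypes: embryos lie in random orientations, so a
#: class must never be encoded purely by motif orientation (at most one
#: stripe class may appear in any one class set).
DEFAULT_MOTIF_MAP = {
    "normal": "ring",
    "dead": "speckle",
    "bmp_lof": "spot_pair",
    "nodal_lof": "eccentric_blob",
    "ra_gain": "stripe_h",
    "wnt_lof": "dark_ring",
    "fgf_lof": "dark_blob",
    "shh_lof": "center_dot",
    "pcp_lof": "dark_stripe",
}


@dataclass(frozen=True)
class EmbryoSchedule:
    """Ground-truth fate of one embryo: class, onset, optional death."""

    final_class: str  # base class, e.g. "nodal_lof"
    onset_frame: int
    death_frame: int | None = None
    severity: str | None = None  # tier for tiered classes

    def __post_init__(self) -> None:
        if self.death_frame is not None and not self.onset_frame < self.death_frame:
            raise ValueError("onset_frame must precede death_frame")

    def label_at(self, frame: int, taxonomy: ClassTaxonomy) -> str:
        """Flat ground-truth label at a frame (unknown / class / dead)."""
        if self.death_frame is not None and frame >= self.death_frame:
            return "dead"
        if frame < self.onset_frame:
            return "unknown"
        if self.final_class in taxonomy.tiered_classes and self.severity:
            return f"{self.final_class}_{self.severity}"
        return self.final_class


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic plate.

    Defaults mirror the emulated acquisition regime (720 frames x 120 s,
    i.e. 2-26 h.p.f. at the default start time) with geometry scaled to a
    512-px frame (a quarter of the emulated 2,048-px sensor, with embryo
    radii scaled to match).  The default embryo count range (3-10) keeps
    non-overlap packing feasible at that frame size.
    """

    seed: int = 0
    n_wells: int = 1
    frames_per_well: int = 720
    interval_s: float = 120.0
    image_size_px: int = 512
    n_embryos_range: tuple[int, int] = (3, 10)
    radius_px_range: tuple[float, float] = (28.0, 42.0)
    classes: tuple[str, ...] = ("normal", "bmp_lof", "nodal_lof", "ra_gain",
                                "wnt_lof", "fgf_lof", "shh_lof", "pcp_lof")
    onset_frame_range: tuple[int, int] | None = None  # default (T//4, T//2)
    death_rate: float = 0.10
    drift_px_per_frame: float = 1.0
    noise_sigma: float = 0.02
    salt_pepper_fraction: float = 0.005
    bit_depth: int = 8
    start_hpf: float = 2.0
    plate_id: str = "phantom"
    motif_map: dict = field(default_factory=lambda: dict(DEFAULT_MOTIF_MAP))
    schedules: tuple | None = None  # explicit per-well schedule lists

    def __post_init__(self) -> None:
        if self.n_embryos_range[0] > self.n_embryos_range[1]:
            raise ValueError("invalid n_embryos_range")
        if self.radius_px_range[0] <= 0 or self.radius_px_range[0] > self.radius_px_range[1]:
            raise ValueError("invalid radius_px_range")


@dataclass
class PhantomResult:
    """Generated frames, ground-truth annotations and schedules per well."""

    spec: PhantomSpec
    frames: dict[str, list[PlateFrame]]
    annotations: dict[str, list[AnnotationRecord]]
    schedules: dict[str, list[EmbryoSchedule]]

    def write(self, out_dir: str | Path) -> None:
        """Write images, per-frame ground-truth JSON and a manifest CSV."""
        out_dir = Path(out_dir)
        img_dir = out_dir / "images"
        ann_dir = out_dir / "annotations"
        img_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for well, frames in self.frames.items():
            for fr in frames:
                name = frame_filename(well, fr.frame_index,
                                      "tif" if self.spec.bit_depth > 8 else "png")
                write_image(img_dir / name, fr.pixels)
                rows.append({"plate_id": fr.plate_id, "well_id": well,
                             "frame_index": fr.frame_index,
                             "acquisition_time_s": fr.acquisition_time_s,
                             "image": f"images/{name}"})
            write_annotation_dir(self.annotations[well], ann_dir, well)
        pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)


# ---------------------------------------------------------------------------
# motif rendering


def _motif_pattern(motif: str, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Signed motif pattern on embryo-local coordinates u, v in [-1, 1].

    Positive values brighten the interior, negative values darken it, so
    classes are distinguished by local structure *and* polarity rather than
    by orientation alone (orientation is destroyed by the random embryo
    pose and by test-time augmentation).
    """
    rho = np.hypot(u, v)
    if motif == "ring":
        return (np.abs(rho - 0.55) < 0.12).astype(float)
    if motif == "spot_pair":
        return ((np.hypot(u - 0.45, v) < 0.18) | (np.hypot(u + 0.45, v) < 0.18)).astype(float)
    if motif == "eccentric_blob":
        return (np.hypot(u - 0.38, v - 0.38) < 0.26).astype(float)
    if motif == "stripe_h":
        return ((np.abs(v) < 0.14) & (rho < 0.9)).astype(float)
    if motif == "stripe_v":
        return ((np.abs(u) < 0.14) & (rho < 0.9)).astype(float)
    if motif == "stripe_diag":
        return ((np.abs(u - v) < 0.20) & (rho < 0.9)).astype(float)
    if motif == "center_dot":
        return (rho < 0.22).astype(float)
    if motif == "dark_ring":
        return -(np.abs(rho - 0.55) < 0.12).astype(float)
    if motif == "dark_blob":
        return -(np.hypot(u - 0.38, v - 0.38) < 0.26).astype(float)
    if motif == "dark_stripe":
        return -((np.abs(v) < 0.14) & (rho < 0.9)).astype(float)
    if motif == "corner_dots":
        pat = np.zeros_like(u)
        for su, sv in ((0.42, 0.42), (-0.42, 0.42), (0.42, -0.42), (-0.42, -0.42)):
            pat = np.maximum(pat, (np.hypot(u - su, v - sv) < 0.15).astype(float))
        return pat
    if motif == "speckle":
        # deterministic fine checker: a low-contrast "disintegrated" texture
        return 0.5 * ((np.floor(u * 8) + np.floor(v * 8)) % 2)
    raise ValueError(f"unknown motif {motif!r}")


def render_motif(base_class: str, severity: str | None, radius_px: float,
                 size_px: int, motif_map: dict | None = None) -> np.ndarray:
    """Noise-free template of one embryo (disk + motif) on a square canvas.

    Used both by the generator and by the template-correlation oracle.
    """
    motif_map = motif_map or DEFAULT_MOTIF_MAP
    c = (size_px - 1) / 2.0
    yy, xx = np.mgrid[0:size_px, 0:size_px].astype(float)
    img = np.full((size_px, size_px), _BG)
    _paint_embryo(img, xx, yy, c, c, radius_px, base_class, severity, motif_map)
    return img


def _paint_embryo(img: np.ndarray, xx: np.ndarray, yy: np.ndarray,
                  cx: float, cy: float, r: float,
                  state: str | None, severity: str | None,
                  motif_map: dict) -> None:
    """Paint one embryo (in state ``state``; None/'unknown' = neutral) in place."""
    d = np.hypot(xx - cx, yy - cy)
    inside = d < r
    rim = inside & (d > r - _RIM_WIDTH)
    img[inside] = _INTERIOR
    img[rim] = _RIM
    if state not in (None, "unknown"):
        motif = motif_map[state]
        interior = inside & ~rim
        u = (xx - cx) / r
        v = (yy - cy) / r
        pat = _motif_pattern(motif, u, v)
        amp = _MOTIF_AMP * _SEVERITY_SCALE.get(severity, 1.0)
        if state == "dead":
            amp = _MOTIF_AMP * 0.5  # low-contrast by construction
        img[interior] += amp * pat[interior]


# ---------------------------------------------------------------------------
# generation


def _well_name(i: int) -> str:
    return f"{chr(ord('A') + i // 12)}-{i % 12 + 1:02d}"


def _pack_centers(rng: np.random.Generator, n: int, radii: np.ndarray,
                  size: int, max_attempts: int = 5000) -> np.ndarray:
    """Rejection-sample non-overlapping, fully interior disk centers."""
    centers: list[tuple[float, float]] = []
    for i in range(n):
        r = radii[i]
        lo, hi = r + 2.0, size - r - 2.0
        if hi <= lo:
            raise ValueError(
                f"infeasible packing: radius {r:.0f} px does not fit in "
                f"a {size}-px frame")
        for _ in range(max_attempts):
            cx = rng.uniform(lo, hi)
            cy = rng.uniform(lo, hi)
            if all(np.hypot(cx - px, cy - py) > r + pr + 2.0
                   for (px, py), pr in zip(centers, radii[: len(centers)])):
                centers.append((cx, cy))
                break
        else:
            raise ValueError(
                f"infeasible packing: could not place embryo {i + 1}/{n} "
                f"(radii {radii[: i + 1].round(1).tolist()}) in a {size}-px frame")
    return np.array(centers, dtype=float).reshape(n, 2)


def _draw_schedules(rng: np.random.Generator, spec: PhantomSpec, n: int,
                    taxonomy: ClassTaxonomy) -> list[EmbryoSchedule]:
    T = spec.frames_per_well
    lo, hi = spec.onset_frame_range or (max(1, T // 4), max(2, T // 2))
    scheds = []
    for _ in range(n):
        cls = spec.classes[rng.integers(0, len(spec.classes))]
        sev = None
        if cls in taxonomy.tiered_classes:
            sev = SEVERITY_TIERS[rng.integers(0, len(SEVERITY_TIERS))]
        onset = int(rng.integers(lo, hi + 1))
        death = None
        if rng.random() < spec.death_rate and onset + 1 < T:
            death = int(rng.integers(onset + 1, T))
        scheds.append(EmbryoSchedule(cls, onset, death, sev))
    return scheds


def generate_phantom(spec: PhantomSpec,
                     taxonomy: ClassTaxonomy | None = None) -> PhantomResult:
    """Render a synthetic plate; byte-deterministic for a fixed seed."""
    taxonomy = taxonomy or ClassTaxonomy()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size_px
    maxval = 2**spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth <= 8 else np.uint16
    yy, xx = np.mgrid[0:size, 0:size].astype(float)

    frames: dict[str, list[PlateFrame]] = {}
    annotations: dict[str, list[AnnotationRecord]] = {}
    schedules: dict[str, list[EmbryoSchedule]] = {}

    for w in range(spec.n_wells):
        well = _well_name(w)
        n = int(rng.integers(spec.n_embryos_range[0], spec.n_embryos_range[1] + 1))
        radii = rng.uniform(*spec.radius_px_range, size=n)
        if spec.schedules is not None:
            scheds = list(spec.schedules[w])
            n = len(scheds)
            radii = radii[:n] if len(radii) >= n else rng.uniform(
                *spec.radius_px_range, size=n)
        else:
            scheds = _draw_schedules(rng, spec, n, taxonomy)
        centers = _pack_centers(rng, n, radii, size)  # may raise pre-render

        # random-walk drift, clamped so disks stay fully inside the frame
        pos = np.empty((spec.frames_per_well, n, 2))
        cur = centers.copy()
        for t in range(spec.frames_per_well):
            if t > 0 and spec.drift_px_per_frame > 0:
                cur = cur + rng.uniform(-spec.drift_px_per_frame,
                                        spec.drift_px_per_frame, size=(n, 2))
                for i in range(n):
                    cur[i] = np.clip(cur[i], radii[i] + 1, size - radii[i] - 2)
            pos[t] = cur

        well_frames: list[PlateFrame] = []
        well_records: list[AnnotationRecord] = []
        for t in range(spec.frames_per_well):
            img = np.full((size, size), _BG)
            embryos = []
            for i in range(n):
                lab = scheds[i].label_at(t, taxonomy)
                base = taxonomy.base_of(lab)
                state = None if base == "unknown" else base
                sev = taxonomy.tier_of(lab)
                _paint_embryo(img, xx, yy, pos[t, i, 0], pos[t, i, 1],
                              radii[i], state, sev, spec.motif_map)
                embryos.append(EmbryoAnnotation(
                    id=i, track_id=i,
                    center_x_px=float(pos[t, i, 0]), center_y_px=float(pos[t, i, 1]),
                    radius_px=float(radii[i]), class_label=lab, severity=sev))
            if spec.noise_sigma > 0:
                img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
            if spec.salt_pepper_fraction > 0:
                mask = rng.random(img.shape) < spec.salt_pepper_fraction
                img[mask] = rng.integers(0, 2, int(mask.sum())).astype(float)
            pixels = np.clip(np.round(img * maxval), 0, maxval).astype(dtype)
            time_s = t * spec.interval_s
            well_frames.append(PlateFrame(pixels, t, time_s, well,
                                          spec.plate_id, spec.bit_depth))
            well_records.append(AnnotationRecord(
                frame_index=t, acquisition_time_s=time_s,
                image=frame_filename(well, t), embryos=embryos))
        frames[well] = well_frames
        annotations[well] = well_records
        schedules[well] = scheds
    return PhantomResult(spec, frames, annotations, schedules)


# ---------------------------------------------------------------------------
# label corruption (test harness for the transition logic)


def corrupt_labels(labels: Sequence[str], flip_rate: float,
                   seed: int | np.random.Generator,
                   label_set: Sequence[str] | None = None) -> list[str]:
    """Independently flip each label to a uniformly chosen *wrong* label.

    ``label_set`` defaults to the distinct labels present in the input.
    """
    if not 0.0 <= flip_rate < 1.0:
        raise ValueError("flip_rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = list(label_set) if label_set is not None else sorted(set(labels))
    out = []
    for lab in labels:
        if flip_rate > 0 and rng.random() < flip_rate:
            wrong = [c for c in pool if c != lab]
            lab = wrong[rng.integers(0, len(wrong))] if wrong else lab
        out.append(lab)
    return out


# ---------------------------------------------------------------------------
# oracle classifier (pixel-statistic; 100 % on noise-free renders post-onset)


def oracle_classify(image_float: np.ndarray, cx: float, cy: float, r: float,
                    candidate_states: Sequence[str],
                    motif_map: dict | None = None) -> str:
    """Classify one rendered embryo by template correlation.

    Extracts the embryo's bounding square and correlates it against the
    noise-free render of each candidate state (``"unknown"`` = neutral disk).
    Pure pixel statistics; independent of the CNN path.
    """
    size = int(round(2 * r)) | 1
    half = size // 2
    icx, icy = int(round(cx)), int(round(cy))
    patch = image_float[max(0, icy - half): icy + half + 1,
                        max(0, icx - half): icx + half + 1]
    best, best_corr = None, -np.inf
    for state in candidate_states:
        base = state if state != "unknown" else None
        tmpl = np.full(patch.shape, _BG)
        yy, xx = np.mgrid[0:patch.shape[0], 0:patch.shape[1]].astype(float)
        _paint_embryo(tmpl, xx, yy, (patch.shape[1] - 1) / 2,
                      (patch.shape[0] - 1) / 2, r, base, None,
                      motif_map or DEFAULT_MOTIF_MAP)
        a = patch - patch.mean()
        b = tmpl - tmpl.mean()
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        corr = (a * b).sum() / denom if denom > 0 else 0.0
        # exact-match bonus: identical pixels beat any correlated motif
        if np.allclose(patch, tmpl, atol=1e-9):
            corr = 2.0
        if corr > best_corr:
            best, best_corr = state, corr
    return best


# ---------------------------------------------------------------------------
# labelled single-embryo crops (training material for the classifier)


def generate_training_crops(n_examples: int, crop_size_px: int,
                            classes: Sequence[str], seed: int,
                            taxonomy: ClassTaxonomy | None = None,
                            noise_sigma: float = 0.02,
                            salt_pepper_fraction: float = 0.005,
                            onset_tau_range: tuple[float, float] = (0.2, 0.5),
                            include_unknown: bool = True):
    """Render labelled single-embryo crops with timestamps.

    Each example draws a fate class, a per-embryo onset time and an
    observation time tau ~ U[0, 1]; the label is ``unknown`` before onset
    and the fate class after.  Returns ``(images, taus, labels)`` with
    images of shape (n, crop, crop) in unit range.
    """
    taxonomy = taxonomy or ClassTaxonomy()
    rng = np.random.default_rng(seed)
    fates = [c for c in classes if c != "unknown"]
    images = np.empty((n_examples, crop_size_px, crop_size_px))
    taus = np.empty(n_examples)
    labels: list[str] = []
    yy, xx = np.mgrid[0:crop_size_px, 0:crop_size_px].astype(float)
    for i in range(n_examples):
        cls = fates[rng.integers(0, len(fates))]
        sev = None
        if cls in taxonomy.tiered_classes:
            sev = SEVERITY_TIERS[rng.integers(0, len(SEVERITY_TIERS))]
        onset_tau = rng.uniform(*onset_tau_range) if include_unknown else 0.0
        tau = rng.uniform(0.0, 1.0)
        pre = tau < onset_tau
        state = None if pre else cls
        # jitter covers the detector's radius-estimate spread downstream
        r = crop_size_px * rng.uniform(0.30, 0.46)
        cx = (crop_size_px - 1) / 2 + rng.uniform(-2, 2)
        cy = (crop_size_px - 1) / 2 + rng.uniform(-2, 2)
        img = np.full((crop_size_px, crop_size_px), _BG)
        _paint_embryo(img, xx, yy, cx, cy, r, state, sev, DEFAULT_MOTIF_MAP)
        if noise_sigma > 0:
            img += rng.normal(0.0, noise_sigma, img.shape)
        if salt_pepper_fraction > 0:
            mask = rng.random(img.shape) < salt_pepper_fraction
            img[mask] = rng.integers(0, 2, int(mask.sum())).astype(float)
        images[i] = np.clip(img, 0.0, 1.0)
        taus[i] = tau
        if pre:
            labels.append("unknown")
        elif sev is not None:
            labels.append(f"{cls}_{sev}")
        else:
            labels.append(cls)
    return images, taus, labels
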