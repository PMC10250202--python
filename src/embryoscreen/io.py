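"""Frames, annotations, configs and reports: on-disk formats and conventions.

Coordinate convention (normative for the whole package): 0-based pixel
indices, origin at the top-left corner, x rightward, y downward, sub-pixel
floats allowed.  The bounding box of a circle (cx, cy, r) is the half-open
square [cx-r, cx+r) x [cy-r, cy+r), clipped to the image.

Images are 8-, 12- or 16-bit grayscale or RGB rasters (TIFF / PNG / JPEG);
12-bit data stored in 16-bit containers is accepted, with the bit depth
declared in the acquisition config rather than sniffed.  Conversion to
unit-range floats is exact division by (2**bit_depth - 1).

Annotations are one JSON file per frame (schema below, version 1).  This
schema is normative for this package::

    {"schema_version": 1, "frame_index": int, "acquisition_time_s": float,
     "image": "relpath", "embryos": [
        {"id": int, "track_id": int (optional),
         "center_x_px": float, "center_y_px": float, "radius_px": float,
         "class": str (optional), "severity": str (optional),
         "score": float (optional), "probs": {label: float} (optional)}]}
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

from .taxonomy import SEVERITY_TIERS

__all__ = [
    "PlateFrame",
    "EmbryoAnnotation",
    "AnnotationRecord",
    "AnnotationSchemaError",
    "read_image",
    "write_image",
    "read_frame_sequence",
    "read_annotations",
    "write_annotations",
    "read_annotation_dir",
    "write_annotation_dir",
    "load_config",
    "frame_filename",
]

SCHEMA_VERSION = 1

#: File-name pattern embedding well id and frame index, e.g. ``A-01_T0007.png``.
FRAME_NAME_RE = re.compile(
    r"^(?P<well>[A-Za-z]+-?\d+)_T(?P<frame>\d+)\.(?P<ext>tif|tiff|png|jpg|jpeg)$",
    re.IGNORECASE,
)


def frame_filename(well_id: str, frame_index: int, ext: str = "png") -> str:
    """Canonical image file name for one well/frame."""
    return f"{well_id}_T{frame_index:04d}.{ext}"


@dataclass
class PlateFrame:
    """One acquired well image plus its time and identity metadata."""

    pixels: np.ndarray  # (H, W) or (H, W, 3) integer raster
    frame_index: int
    acquisition_time_s: float
    well_id: str
    plate_id: str = ""
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.frame_index < 0 or self.acquisition_time_s < 0:
            raise ValueError("frame_index and acquisition_time_s must be >= 0")

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    def to_float(self) -> np.ndarray:
        """Unit-range float image: exact division by (2**bit_depth - 1)."""
        return self.pixels.astype(np.float64) / float(2**self.bit_depth - 1)


@dataclass
class EmbryoAnnotation:
    """A circle hypothesis for one embryo in one frame, optionally labelled."""

    id: int
    center_x_px: float
    center_y_px: float
    radius_px: float
    track_id: int | None = None
    class_label: str | None = None
    severity: str | None = None
    score: float | None = None
    probs: dict[str, float] | None = None


@dataclass
class AnnotationRecord:
    """All embryo annotations of one frame."""

    frame_index: int
    acquisition_time_s: float = 0.0
    image: str = ""
    embryos: list[EmbryoAnnotation] = field(default_factory=list)


class AnnotationSchemaError(ValueError):
    """Raised when an annotation file violates the schema; lists the fields."""


# ---------------------------------------------------------------------------
# images


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG/JPEG image as an integer array, preserving bit depth."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            return np.asarray(tifffile.imread(path))
        import imageio.v3 as iio

        return np.asarray(iio.imread(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - depends on file corruption
        raise IOError(f"unreadable image file: {path}") from exc


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, pixels)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, pixels)


# ---------------------------------------------------------------------------
# frame sequences


def read_frame_sequence(
    directory: str | Path, layout_config: dict | None = None
) -> dict[str, list[PlateFrame]]:
    """Read a directory of well images into ordered per-well frame streams.

    File names must follow ``<well>_T<frame>.<ext>`` (see ``frame_filename``).
    ``layout_config`` is the ``acquisition`` config section; recognised keys:
    ``interval_s`` (default 120), ``plate_id``, ``bit_depth`` (default 8).
    When no per-file time metadata exists, acquisition_time_s is
    frame_index * interval_s.  Missing frame indices are warned about and
    recorded as gaps, not errors; an unreadable file raises naming its path.
    """
    directory = Path(directory)
    cfg = dict(layout_config or {})
    interval_s = float(cfg.get("interval_s", 120.0))
    plate_id = str(cfg.get("plate_id", directory.name))
    bit_depth = int(cfg.get("bit_depth", 8))

    matches = []
    for p in sorted(directory.iterdir()) if directory.exists() else []:
        m = FRAME_NAME_RE.match(p.name)
        if m:
            matches.append((m.group("well"), int(m.group("frame")), p))
    if not matches:
        warnings.warn(f"no well images found in {directory}", stacklevel=2)
        return {}

    wells: dict[str, list[PlateFrame]] = {}
    for well in sorted({w for w, _, _ in matches}):
        entries = sorted(
            ((f, p) for w, f, p in matches if w == well), key=lambda e: e[0]
        )
        indices = [f for f, _ in entries]
        expected = range(indices[0], indices[-1] + 1)
        missing = sorted(set(expected) - set(indices))
        if missing:
            warnings.warn(
                f"well {well}: missing frame indices {missing}", stacklevel=2
            )
        frames = [
            PlateFrame(
                pixels=read_image(p),
                frame_index=f,
                acquisition_time_s=f * interval_s,
                well_id=well,
                plate_id=plate_id,
                bit_depth=bit_depth,
            )
            for f, p in entries
        ]
        wells[well] = frames
    return wells


# ---------------------------------------------------------------------------
# annotations (one JSON file per frame)

_REQUIRED_EMBRYO = {"id", "center_x_px", "center_y_px", "radius_px"}


def _embryo_to_dict(e: EmbryoAnnotation) -> dict:
    d: dict = {
        "id": int(e.id),
        "center_x_px": float(e.center_x_px),
        "center_y_px": float(e.center_y_px),
        "radius_px": float(e.radius_px),
    }
    if e.track_id is not None:
        d["track_id"] = int(e.track_id)
    if e.class_label is not None:
        d["class"] = e.class_label
    if e.severity is not None:
        d["severity"] = e.severity
    if e.score is not None:
        d["score"] = float(e.score)
    if e.probs is not None:
        d["probs"] = {k: float(v) for k, v in e.probs.items()}
    return d


def _embryo_from_dict(d: dict, where: str) -> EmbryoAnnotation:
    bad = sorted(_REQUIRED_EMBRYO - set(d))
    if bad:
        raise AnnotationSchemaError(f"{where}: missing embryo fields {bad}")
    sev = d.get("severity")
    if sev is not None and sev not in SEVERITY_TIERS:
        raise AnnotationSchemaError(f"{where}: invalid severity {sev!r}")
    score = d.get("score")
    if score is not None and not 0.0 <= float(score) <= 1.0:
        raise AnnotationSchemaError(f"{where}: score {score} outside [0, 1]")
    return EmbryoAnnotation(
        id=int(d["id"]),
        center_x_px=float(d["center_x_px"]),
        center_y_px=float(d["center_y_px"]),
        radius_px=float(d["radius_px"]),
        track_id=int(d["track_id"]) if "track_id" in d else None,
        class_label=d.get("class"),
        severity=sev,
        score=float(score) if score is not None else None,
        probs=d.get("probs"),
    )


def write_annotations(record: AnnotationRecord, path: str | Path) -> None:
    """Write one frame's annotations as a JSON file."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "frame_index": int(record.frame_index),
        "acquisition_time_s": float(record.acquisition_time_s),
        "image": record.image,
        "embryos": [_embryo_to_dict(e) for e in record.embryos],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations(path: str | Path) -> AnnotationRecord:
    """Read one frame's annotation JSON, validating against the schema."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationSchemaError(f"{path}: not valid JSON ({exc})") from exc
    bad = sorted({"frame_index", "embryos"} - set(payload))
    if bad:
        raise AnnotationSchemaError(f"{path}: missing fields {bad}")
    return AnnotationRecord(
        frame_index=int(payload["frame_index"]),
        acquisition_time_s=float(payload.get("acquisition_time_s", 0.0)),
        image=payload.get("image", ""),
        embryos=[
            _embryo_from_dict(d, f"{path}[embryos][{i}]")
            for i, d in enumerate(payload["embryos"])
        ],
    )


def annotation_filename(well_id: str, frame_index: int) -> str:
    return f"{well_id}_T{frame_index:04d}.json"


def write_annotation_dir(
    records: Sequence[AnnotationRecord], directory: str | Path, well_id: str
) -> None:
    """Write one JSON file per frame into ``directory`` for one well."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in records:
        write_annotations(rec, directory / annotation_filename(well_id, rec.frame_index))


def read_annotation_dir(
    directory: str | Path, well_id: str | None = None
) -> dict[str, list[AnnotationRecord]]:
    """Read all per-frame annotation files, grouped per well, frame-ordered."""
    directory = Path(directory)
    out: dict[str, list[tuple[int, AnnotationRecord]]] = {}
    for p in sorted(directory.glob("*.json")):
        m = re.match(r"^(?P<well>.+)_T(?P<frame>\d+)\.json$", p.name)
        if not m:
            continue
        well = m.group("well")
        if well_id is not None and well != well_id:
            continue
        out.setdefault(well, []).append((int(m.group("frame")), read_annotations(p)))
    return {
        w: [rec for _, rec in sorted(entries, key=lambda e: e[0])]
        for w, entries in sorted(out.items())
    }


# ---------------------------------------------------------------------------
# configuration


def load_config(path: str | Path) -> dict:
    """Load the YAML pipeline config (sections: acquisition / detection /
    tracking / classifier / transition / taxonomy / screen)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping of sections")
    return cfg
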