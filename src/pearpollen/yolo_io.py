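"""Readers/writers for YOLO-format detection and annotation text files.

One file per image; each row is ``class_id cx cy w h [confidence]`` with all
geometry normalized to [0, 1] relative to the image size.  Ground-truth
annotation files use the identical dialect minus the confidence column.
Internally boxes are denormalized to pixel corner coordinates (top-left
origin, half-open).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

from .detection import Box, Detection
from .reference import FloweringStage

__all__ = ["MalformedRowError", "read_detection_file", "write_detection_file"]

logger = logging.getLogger(__name__)

DEFAULT_IMAGE_SIZE = 640


class MalformedRowError(ValueError):
    """A detection-file row that cannot be parsed (strict mode aborts on it)."""


def _parse_row(
    line: str, path: Path, line_no: int, image_size: float, image_id: Optional[str]
) -> Optional[Detection]:
    fields = line.split()
    if len(fields) not in (5, 6):
        raise MalformedRowError(
            f"{path}:{line_no}: expected 5 or 6 fields, got {len(fields)}"
        )
    try:
        class_id = int(fields[0])
        cx, cy, w, h = (float(v) for v in fields[1:5])
        confidence = float(fields[5]) if len(fields) == 6 else None
    except ValueError as exc:
        raise MalformedRowError(f"{path}:{line_no}: {exc}") from None
    if not 0 <= class_id <= 4:
        raise MalformedRowError(
            f"{path}:{line_no}: class id {class_id} outside 0-4"
        )
    for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
        if not 0.0 <= v <= 1.0:
            raise MalformedRowError(
                f"{path}:{line_no}: {name}={v} outside normalized range [0, 1]"
            )
    if w <= 0 or h <= 0:
        raise MalformedRowError(f"{path}:{line_no}: zero-size box")
    if confidence is not None and not 0.0 <= confidence <= 1.0:
        raise MalformedRowError(
            f"{path}:{line_no}: confidence {confidence} outside [0, 1]"
        )
    box = Box.from_center(cx * image_size, cy * image_size,
                          w * image_size, h * image_size)
    return Detection(
        stage=FloweringStage(class_id),
        confidence=confidence,
        box=box,
        image_id=image_id,
    )


def read_detection_file(
    path: Union[str, Path],
    image_size: float = DEFAULT_IMAGE_SIZE,
    strict: bool = False,
    image_id: Optional[str] = None,
) -> list[Detection]:
    """Parse one YOLO-format file into pixel-space :class:`Detection` records.

    ``image_id`` defaults to the file stem.  Malformed rows abort with a
    file/line diagnostic when ``strict`` is true, otherwise they are skipped
    with a logged warning.
    """
    path = Path(path)
    if image_id is None:
        image_id = path.stem
    detections: list[Detection] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                det = _parse_row(line, path, line_no, image_size, image_id)
            except MalformedRowError as exc:
                if strict:
                    raise
                logger.warning("skipping malformed row: %s", exc)
                warnings.warn(str(exc), stacklevel=2)
                continue
            detections.append(det)
    return detections


def write_detection_file(
    detections: Sequence[Detection],
    path: Union[str, Path],
    image_size: float = DEFAULT_IMAGE_SIZE,
    precision: int = 6,
) -> None:
    """Write detections back to the YOLO dialect (normalized center format).

    Rows with ``confidence=None`` are written in the 5-field ground-truth
    dialect.  Round-trips are value-identical at the declared precision.
    """
    path = Path(path)
    lines = []
    for det in detections:
        cx, cy = det.box.center
        w = det.box.x_max - det.box.x_min
        h = det.box.y_max - det.box.y_min
        fields = [
            str(det.stage.class_index),
            f"{cx / image_size:.{precision}f}",
            f"{cy / image_size:.{precision}f}",
            f"{w / image_size:.{precision}f}",
            f"{h / image_size:.{precision}f}",
        ]
        if det.confidence is not None:
            fields.append(f"{det.confidence:.{precision}f}")
        lines.append(" ".join(fields))
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
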