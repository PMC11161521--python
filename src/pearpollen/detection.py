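"""Bounding boxes, IoU, per-class non-maximum suppression and stage tallies.

Boxes are axis-aligned rectangles in corner format, half-open
``[x_min, x_max) × [y_min, y_max)``, origin at the image's top-left corner.
Coordinates may be pixels or normalized units; all operations here are
scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .reference import FloweringStage, StageCounts

__all__ = ["Box", "Detection", "iou", "nms", "counts_from_detections"]


@dataclass(frozen=True)
class Box:
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max}) must satisfy x_min < x_max "
                "and y_min < y_max"
            )

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @classmethod
    def from_center(cls, cx: float, cy: float, w: float, h: float) -> "Box":
        return cls(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2, (self.y_min + self.y_max) / 2)


@dataclass(frozen=True)
class Detection:
    """One detected flower: stage label, confidence, box, source image.

    ``confidence`` is ``None`` for ground-truth annotations (the ground-truth
    file dialect carries no confidence column).
    """

    stage: FloweringStage
    confidence: Optional[float]
    box: Box
    image_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; symmetric, 0 when disjoint, 1 when equal."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def nms(
    detections: Sequence[Detection],
    iou_threshold: float = 0.5,
    confidence_threshold: float = 0.25,
) -> list[Detection]:
    """Greedy per-class non-maximum suppression.

    Detections below ``confidence_threshold`` are dropped first.  Within each
    class, boxes are visited in descending confidence (ties broken by input
    order, which makes the result deterministic); a box is kept unless it has
    IoU ≥ ``iou_threshold`` with an already-kept box of the same class.
    Cross-class overlaps are never suppressed.  Output is sorted by descending
    confidence, ties again in input order.
    """
    for name, t in (("iou_threshold", iou_threshold),
                    ("confidence_threshold", confidence_threshold)):
        if not (0.0 <= t <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {t}")

    candidates = [
        (i, d) for i, d in enumerate(detections)
        if d.confidence is None or d.confidence >= confidence_threshold
    ]
    # descending confidence, stable in input order; confidence-free
    # (ground-truth) records rank as confidence 1.
    candidates.sort(key=lambda item: (-(item[1].confidence
                                        if item[1].confidence is not None
                                        else 1.0), item[0]))
    kept: list[tuple[int, Detection]] = []
    for idx, det in candidates:
        suppressed = any(
            k.stage == det.stage and iou(k.box, det.box) >= iou_threshold
            for _, k in kept
        )
        if not suppressed:
            kept.append((idx, det))
    return [d for _, d in kept]


def counts_from_detections(detections: Sequence[Detection]) -> StageCounts:
    """Tally post-processed detections into per-stage counts (total = input length)."""
    counts = {s: 0 for s in FloweringStage}
    for det in detections:
        counts[det.stage] += 1
    return StageCounts(counts)
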