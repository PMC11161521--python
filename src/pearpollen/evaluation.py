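"""Accuracy statistics for count-based pollen estimation.

Implements the study's evaluation toolkit:

* **Estimation error** (signed %): ``−(1 − detected/actual) × 100`` on flower
  counts; a pollen-mass ratio variant is exposed separately because the two
  forms only coincide when detected and actual stage proportions match.
* **Corrected error**: the occlusion correction acts additively on the error
  percentage — ``error + 100 × (factor − 1)`` — even though it is
  multiplicative on mass; both behaviours are deliberate and documented.
* **Accuracy rate** (%): correctly-labelled detections over all detections
  (missed flowers are excluded from the denominator).
* **Stage percentages** and their signed differences, reported to 1 decimal.
* **Confusion matrix with background**: IoU-matched stage confusion where
  unmatched truth falls in a background column (undetected flowers) and
  unmatched detections in a background row (spurious detections).
* **mAP50**: mean average precision at IoU 0.5 over the five stage classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .detection import Box, Detection, iou
from .reference import FloweringStage, StageCounts

__all__ = [
    "estimation_error_pct",
    "estimation_error_from_pollen",
    "corrected_error_pct",
    "accuracy_rate_pct",
    "StagePercentages",
    "stage_percentages",
    "stage_percentage_errors",
    "BACKGROUND",
    "ConfusionMatrix",
    "confusion_with_background",
    "map50",
]

#: Sentinel label for undetected flowers / spurious detections.
BACKGROUND = "background"

TruthBox = Union[Detection, tuple]


def _round_half_up(x: float, ndigits: int) -> float:
    scale = 10.0 ** ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# Scalar error/accuracy statistics
# ---------------------------------------------------------------------------

def estimation_error_pct(n_detected: int, n_actual: int) -> float:
    """Signed percentage error of the detected flower count vs. ground truth.

    ``−(1 − n_detected/n_actual) × 100``: negative when flowers are missed,
    0 for perfect detection, −100 when nothing is detected.
    """
    if n_actual <= 0:
        raise ValueError("estimation error undefined for n_actual = 0")
    return -(1.0 - n_detected / n_actual) * 100.0


def estimation_error_from_pollen(estimated_mg: float, actual_mg: float) -> float:
    """Pollen-mass form of the estimation error: ``−(1 − est/actual) × 100``.

    Agrees with :func:`estimation_error_pct` exactly when detected and actual
    stage proportions are identical; otherwise the two differ and callers
    should report which form they used.
    """
    if actual_mg <= 0:
        raise ValueError("estimation error undefined for zero actual pollen")
    return -(1.0 - estimated_mg / actual_mg) * 100.0


def corrected_error_pct(raw_error: float, factor: float) -> float:
    """Estimation error after occlusion correction, in percentage points.

    Additive: ``raw_error + 100 × (factor − 1)``.  The correction is exactly
    zeroing when ``factor = n_actual / n_detected``.
    """
    if factor < 1.0:
        raise ValueError(f"occlusion factor must be >= 1, got {factor}")
    return raw_error + 100.0 * (factor - 1.0)


def accuracy_rate_pct(n_correct: int, n_detected: int) -> float:
    """Percentage of detected flowers whose stage label is correct."""
    if n_detected <= 0:
        raise ValueError("accuracy rate undefined with zero detections")
    if not (0 <= n_correct <= n_detected):
        raise ValueError(
            f"n_correct={n_correct} must lie in [0, n_detected={n_detected}]"
        )
    return n_correct / n_detected * 100.0


# ---------------------------------------------------------------------------
# Stage-percentage comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StagePercentages:
    """Per-stage share of total flowers (%), at 1-decimal report precision."""

    pct: Mapping[FloweringStage, float]
    total: int


def stage_percentages(counts: StageCounts, ndigits: int = 1) -> StagePercentages:
    """Per-stage percentages of the total flower count, rounded for report."""
    total = counts.total
    if total <= 0:
        raise ValueError("stage percentages undefined for zero total count")
    pct = {
        s: _round_half_up(counts[s] / total * 100.0, ndigits)
        for s in FloweringStage
    }
    return StagePercentages(pct=pct, total=total)


def stage_percentage_errors(
    estimated: StagePercentages, actual: StagePercentages, ndigits: int = 1
) -> dict[FloweringStage, float]:
    """Signed percentage-point difference (estimated − actual) per stage."""
    return {
        s: _round_half_up(estimated.pct[s] - actual.pct[s], ndigits)
        for s in FloweringStage
    }


# ---------------------------------------------------------------------------
# Confusion matrix with background
# ---------------------------------------------------------------------------

_LABELS = [s for s in FloweringStage] + [BACKGROUND]


def _label_index(label) -> int:
    return 5 if label == BACKGROUND else int(label)


@dataclass(frozen=True)
class ConfusionMatrix:
    """6×6 tally: rows = true label (+background), columns = predicted.

    ``counts[i, j]`` is the number of (truth, detection) outcomes with true
    label i and predicted label j; index 5 is background on either axis.
    ``counts[5, 5]`` is structurally zero.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (6, 6):
            raise ValueError(f"confusion matrix must be 6x6, got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    def __getitem__(self, key) -> int:
        true_label, pred_label = key
        return int(self.counts[_label_index(true_label), _label_index(pred_label)])

    def row_proportions(self) -> np.ndarray:
        """Row-normalized proportions; all-zero rows stay zero."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            props = np.where(totals > 0, self.counts / totals, 0.0)
        return props

    def to_frame(self, proportions: bool = False) -> pd.DataFrame:
        labels = [getattr(lbl, "label", lbl) for lbl in _LABELS]
        data = self.row_proportions() if proportions else self.counts
        return pd.DataFrame(data, index=labels, columns=labels)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


def _as_truth_pairs(truth: Sequence[TruthBox]) -> list[tuple[FloweringStage, Box]]:
    pairs = []
    for item in truth:
        if isinstance(item, Detection):
            pairs.append((item.stage, item.box))
        else:
            stage, box = item
            pairs.append((FloweringStage(stage), box))
    return pairs


def confusion_with_background(
    truth: Sequence[TruthBox],
    detections: Sequence[Detection],
    iou_threshold: float = 0.5,
) -> ConfusionMatrix:
    """Stage confusion matrix from one image's truth boxes and detections.

    Matching is greedy, one-to-one and label-agnostic: candidate pairs with
    IoU ≥ ``iou_threshold`` are taken in descending IoU order (ties broken by
    truth then detection input order).  Matched pairs tally
    (true stage, predicted stage); unmatched truth boxes land in the
    background column, unmatched detections in the background row.
    """
    if not (0.0 <= iou_threshold <= 1.0):
        raise ValueError(f"iou_threshold must be in [0, 1], got {iou_threshold}")
    truth_pairs = _as_truth_pairs(truth)

    candidates = []
    for t_idx, (_, t_box) in enumerate(truth_pairs):
        for d_idx, det in enumerate(detections):
            overlap = iou(t_box, det.box)
            if overlap >= iou_threshold and overlap > 0:
                candidates.append((overlap, t_idx, d_idx))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    matched_truth: dict[int, int] = {}
    matched_det: set[int] = set()
    for _, t_idx, d_idx in candidates:
        if t_idx in matched_truth or d_idx in matched_det:
            continue
        matched_truth[t_idx] = d_idx
        matched_det.add(d_idx)

    counts = np.zeros((6, 6), dtype=np.int64)
    for t_idx, (t_stage, _) in enumerate(truth_pairs):
        if t_idx in matched_truth:
            p_stage = detections[matched_truth[t_idx]].stage
            counts[int(t_stage), int(p_stage)] += 1
        else:
            counts[int(t_stage), 5] += 1
    for d_idx, det in enumerate(detections):
        if d_idx not in matched_det:
            counts[5, int(det.stage)] += 1
    return ConfusionMatrix(counts)


# ---------------------------------------------------------------------------
# mAP50
# ---------------------------------------------------------------------------

def _group_by_image(items):
    groups: dict[Optional[str], list] = {}
    for item in items:
        image_id = item.image_id if isinstance(item, Detection) else None
        groups.setdefault(image_id, []).append(item)
    return groups


def _average_precision(
    tp_flags: np.ndarray, n_truth: int, interpolation: str
) -> float:
    if n_truth == 0:
        return float("nan")
    if tp_flags.size == 0:
        return 0.0
    tp = np.cumsum(tp_flags)
    fp = np.cumsum(1 - tp_flags)
    recall = tp / n_truth
    precision = tp / (tp + fp)

    if interpolation == "all_point":
        # precision envelope integrated over recall steps
        r = np.concatenate(([0.0], recall, [1.0]))
        p = np.concatenate(([0.0], precision, [0.0]))
        for i in range(p.size - 2, -1, -1):
            p[i] = max(p[i], p[i + 1])
        steps = np.nonzero(r[1:] != r[:-1])[0]
        return float(np.sum((r[steps + 1] - r[steps]) * p[steps + 1]))
    if interpolation == "101point":
        grid = np.linspace(0.0, 1.0, 101)
        interp = np.array(
            [precision[recall >= r].max() if (recall >= r).any() else 0.0
             for r in grid]
        )
        return float(interp.mean())
    raise ValueError(
        f"interpolation must be 'all_point' or '101point', got {interpolation!r}"
    )


def map50(
    truth: Sequence[TruthBox],
    detections: Sequence[Detection],
    iou_threshold: float = 0.5,
    interpolation: str = "all_point",
) -> float:
    """Mean average precision over stage classes at an IoU-0.5 match criterion.

    Detections are ranked by descending confidence per class; each is matched
    to the free same-class truth box of highest IoU within its image (TP if
    IoU ≥ ``iou_threshold``, FP otherwise; a truth box matches at most once).
    AP uses all-point interpolation by default; a 101-point variant is
    available.  The mean runs over the classes present in truth.
    """
    truth_items = list(truth)
    if not truth_items:
        raise ValueError("mAP undefined without any truth boxes")
    det_items = list(detections)
    for det in det_items:
        if det.confidence is None:
            raise ValueError("mAP requires confidences on all detections")

    truth_by_image: dict[Optional[str], list[tuple[FloweringStage, Box]]] = {}
    for item in truth_items:
        image_id = item.image_id if isinstance(item, Detection) else None
        pair = (item.stage, item.box) if isinstance(item, Detection) else (
            FloweringStage(item[0]), item[1])
        truth_by_image.setdefault(image_id, []).append(pair)

    aps = []
    for cls in FloweringStage:
        n_truth = sum(
            1 for pairs in truth_by_image.values() for s, _ in pairs if s == cls
        )
        if n_truth == 0:
            continue
        cls_dets = [(i, d) for i, d in enumerate(det_items) if d.stage == cls]
        cls_dets.sort(key=lambda item: (-item[1].confidence, item[0]))
        used: set[tuple[Optional[str], int]] = set()
        flags = np.zeros(len(cls_dets), dtype=np.int64)
        for rank, (_, det) in enumerate(cls_dets):
            pairs = truth_by_image.get(det.image_id, [])
            best_iou, best_idx = 0.0, None
            for t_idx, (s, t_box) in enumerate(pairs):
                if s != cls or (det.image_id, t_idx) in used:
                    continue
                overlap = iou(t_box, det.box)
                if overlap > best_iou:
                    best_iou, best_idx = overlap, t_idx
            if best_idx is not None and best_iou >= iou_threshold:
                flags[rank] = 1
                used.add((det.image_id, best_idx))
        aps.append(_average_precision(flags, n_truth, interpolation))
    return float(np.mean(aps))
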