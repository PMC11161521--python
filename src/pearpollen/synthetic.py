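"""Synthetic flowering-branch scenes and a stochastic detector simulator.

Real inputs to the pipeline are photographs of flowering pear branches run
through a trained object detector.  This module replaces both with a
desk-scale generative stand-in:

* :func:`generate_scene` scatters ``n_flowers`` ground-truth boxes over the
  image, draws each flower's stage from a five-way distribution and hides a
  Bernoulli(q) fraction behind "branches" (occluded flowers never reach the
  detector — this is exactly the bias the occlusion correction targets).
* :func:`simulate_detector` emits noisy detections for the visible flowers:
  per-stage miss probabilities, a row-stochastic stage-confusion matrix,
  box-coordinate jitter and stochastic confidences.  Defaults reproduce the
  published per-stage detector operating point (Early 80% / Late 86% correct,
  Best 69% with 18% Best→Early, Other 54%, shortfall assigned to missed
  detections).

Everything is driven by explicit integer seeds; equal seeds give identical
scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .detection import Box, Detection, iou
from .evaluation import ConfusionMatrix, confusion_with_background
from .reference import FloweringStage

__all__ = [
    "SceneParams",
    "DetectorNoiseParams",
    "TruthFlower",
    "SyntheticScene",
    "default_noise_params",
    "generate_scene",
    "simulate_detector",
    "recover_confusion",
]

#: Ground-truth stage mix: the measured branch-set proportions
#: (Early .30, Best .21, Late .40, Too late .04) plus a small Other share so
#: the side/back-view pricing rule is exercised.
DEFAULT_STAGE_DISTRIBUTION = (0.30, 0.21, 0.40, 0.04, 0.05)

#: Midpoint of the assumed 12.5–25% hidden-flower band.
DEFAULT_OCCLUSION_FRACTION = 0.1875


@dataclass(frozen=True)
class SceneParams:
    """Ground-truth scene geometry and composition.

    Defaults describe one flowering branch: 62 flowers (the visually counted
    total of the reference branch set), the measured stage mix, and an
    occlusion fraction at the midpoint of the assumed 12.5–25% band, on a
    640×640 image with flower boxes 24–64 px across.
    """

    n_flowers: int = 62
    stage_distribution: Sequence[float] = DEFAULT_STAGE_DISTRIBUTION
    occlusion_fraction: float = DEFAULT_OCCLUSION_FRACTION
    image_size: int = 640
    box_size_range: tuple[float, float] = (24.0, 64.0)
    max_overlap_iou: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        dist = np.asarray(self.stage_distribution, dtype=float)
        if dist.shape != (5,) or (dist < 0).any() or abs(dist.sum() - 1.0) > 1e-9:
            raise ValueError(
                "stage_distribution must be 5 non-negative probabilities summing to 1"
            )
        if not (0.0 <= self.occlusion_fraction <= 1.0):
            raise ValueError("occlusion_fraction must be in [0, 1]")
        lo, hi = self.box_size_range
        if not (0 < lo <= hi <= self.image_size):
            raise ValueError(
                "box sizes must be positive and no larger than the image"
            )
        if self.n_flowers < 0:
            raise ValueError("n_flowers must be non-negative")


def _default_confusion() -> np.ndarray:
    # Conditional on being detected at all; marginals (row × (1 - miss))
    # reproduce the published rates, e.g. Best→Early 0.87 × 0.18/0.87 = 0.18.
    c = np.eye(5)
    c[1, 0] = 0.18 / 0.87
    c[1, 1] = 0.69 / 0.87
    return c


@dataclass(frozen=True)
class DetectorNoiseParams:
    """Stochastic detector model.

    ``miss_rate[s]`` is the probability a visible stage-s flower yields no
    detection; otherwise its label is drawn from row s of ``confusion``
    (row-stochastic, conditional on detection).  Defaults give marginal
    correct-label rates Early .80, Best .69 (+.18 to Early), Late .86,
    Too late .80, Other .54, with the remaining mass missed.  Box corners are
    jittered with Gaussian noise of scale ``jitter`` px.  Confidences are
    uniform on ``confidence_correct`` for correctly labelled detections and
    ``confidence_confused`` otherwise.  ``spurious_rate`` adds that expected
    number of false detections per flower, uniformly placed (default 0).
    """

    confusion: np.ndarray = field(default_factory=_default_confusion)
    miss_rate: Sequence[float] = (0.20, 0.13, 0.14, 0.20, 0.46)
    jitter: float = 2.0
    confidence_correct: tuple[float, float] = (0.5, 1.0)
    confidence_confused: tuple[float, float] = (0.25, 0.75)
    spurious_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        conf = np.asarray(self.confusion, dtype=float)
        if conf.shape != (5, 5) or (conf < 0).any():
            raise ValueError("confusion must be a non-negative 5x5 matrix")
        if not np.allclose(conf.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion rows must each sum to 1")
        object.__setattr__(self, "confusion", conf)
        miss = np.asarray(self.miss_rate, dtype=float)
        if miss.shape != (5,) or ((miss < 0) | (miss > 1)).any():
            raise ValueError("miss_rate must be 5 probabilities in [0, 1]")
        object.__setattr__(self, "miss_rate", miss)
        if self.jitter < 0 or self.spurious_rate < 0:
            raise ValueError("jitter and spurious_rate must be non-negative")


def default_noise_params(seed: int = 0) -> DetectorNoiseParams:
    """Detector noise at the published per-stage operating point."""
    return DetectorNoiseParams(seed=seed)


@dataclass(frozen=True)
class TruthFlower:
    stage: FloweringStage
    box: Box
    occluded: bool


@dataclass(frozen=True)
class SyntheticScene:
    """Ground-truth flowers plus (optionally) simulated detections.

    ``detection_links[i]`` gives the truth index of detection i, or ``None``
    for a spurious detection; occluded flowers never appear among the links.
    """

    params: SceneParams
    truth: tuple[TruthFlower, ...]
    noise: Optional[DetectorNoiseParams] = None
    detections: tuple[Detection, ...] = ()
    detection_links: tuple[Optional[int], ...] = ()

    @property
    def visible_truth(self) -> list[TruthFlower]:
        return [f for f in self.truth if not f.occluded]

    def truth_pairs(self, include_occluded: bool = False) -> list[tuple[FloweringStage, Box]]:
        return [
            (f.stage, f.box)
            for f in self.truth
            if include_occluded or not f.occluded
        ]


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Place ground-truth flower boxes; deterministic for a fixed seed.

    Boxes are rejection-sampled so no pair overlaps beyond
    ``params.max_overlap_iou`` (flowers cluster on branches but are not
    coincident).  Raises if the scene cannot be packed.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.box_size_range
    boxes: list[Box] = []
    max_attempts = 200 * max(params.n_flowers, 1)
    attempts = 0
    while len(boxes) < params.n_flowers:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {params.n_flowers} boxes of size "
                f"{params.box_size_range} in a {params.image_size}px image "
                f"under IoU cap {params.max_overlap_iou}"
            )
        w = rng.uniform(lo, hi)
        h = rng.uniform(lo, hi)
        x = rng.uniform(0.0, params.image_size - w)
        y = rng.uniform(0.0, params.image_size - h)
        candidate = Box(x, y, x + w, y + h)
        if all(iou(candidate, b) <= params.max_overlap_iou for b in boxes):
            boxes.append(candidate)

    stages = rng.choice(5, size=params.n_flowers, p=np.asarray(
        params.stage_distribution, dtype=float))
    occluded = rng.random(params.n_flowers) < params.occlusion_fraction
    truth = tuple(
        TruthFlower(FloweringStage(int(s)), box, bool(o))
        for s, box, o in zip(stages, boxes, occluded)
    )
    return SyntheticScene(params=params, truth=truth)


def _jitter_box(box: Box, scale: float, image_size: float, rng) -> Box:
    if scale == 0:
        return box
    for _ in range(100):
        dx = rng.normal(0.0, scale, size=4)
        x0 = min(max(box.x_min + dx[0], 0.0), image_size)
        y0 = min(max(box.y_min + dx[1], 0.0), image_size)
        x1 = min(max(box.x_max + dx[2], 0.0), image_size)
        y1 = min(max(box.y_max + dx[3], 0.0), image_size)
        if x0 < x1 and y0 < y1:
            return Box(x0, y0, x1, y1)
    return box


def simulate_detector(
    scene: SyntheticScene, noise: Optional[DetectorNoiseParams] = None
) -> SyntheticScene:
    """Fill a scene's detections by running the noise model over visible truth.

    Occluded flowers emit nothing.  Each visible flower is independently
    missed with its stage's miss rate; otherwise one detection is emitted
    with a (possibly confused) label, jittered box and stochastic confidence.
    Spurious detections, if enabled, are appended with random stage and box.
    Deterministic for fixed scene/noise seeds.
    """
    if noise is None:
        noise = default_noise_params(seed=scene.params.seed + 1)
    rng = np.random.default_rng(noise.seed)
    size = float(scene.params.image_size)

    detections: list[Detection] = []
    links: list[Optional[int]] = []
    for idx, flower in enumerate(scene.truth):
        if flower.occluded:
            continue
        s = int(flower.stage)
        if rng.random() < noise.miss_rate[s]:
            continue
        predicted = FloweringStage(int(rng.choice(5, p=noise.confusion[s])))
        lo, hi = (noise.confidence_correct if predicted == flower.stage
                  else noise.confidence_confused)
        confidence = float(rng.uniform(lo, hi))
        box = _jitter_box(flower.box, noise.jitter, size, rng)
        detections.append(Detection(stage=predicted, confidence=confidence, box=box))
        links.append(idx)

    n_spurious = rng.poisson(noise.spurious_rate * len(scene.truth)) \
        if noise.spurious_rate > 0 else 0
    lo, hi = scene.params.box_size_range
    for _ in range(n_spurious):
        w, h = rng.uniform(lo, hi, size=2)
        x = rng.uniform(0.0, size - w)
        y = rng.uniform(0.0, size - h)
        detections.append(Detection(
            stage=FloweringStage(int(rng.integers(5))),
            confidence=float(rng.uniform(*noise.confidence_confused)),
            box=Box(x, y, x + w, y + h),
        ))
        links.append(None)

    return replace(
        scene, noise=noise,
        detections=tuple(detections), detection_links=tuple(links),
    )


def recover_confusion(
    scenes: Sequence[SyntheticScene], iou_threshold: float = 0.5
) -> ConfusionMatrix:
    """Pool IoU-matched stage confusion over scenes (visible truth only).

    Row-normalized proportions of the result estimate the detector's marginal
    per-stage label rates, with the background column estimating the miss
    rates — the construction used to read a detector's operating point off
    annotated validation images.
    """
    scenes = list(scenes)
    if not scenes:
        raise ValueError("cannot recover confusion from an empty scene list")
    total = ConfusionMatrix(np.zeros((6, 6), dtype=np.int64))
    for scene in scenes:
        total = total + confusion_with_background(
            scene.truth_pairs(), scene.detections, iou_threshold
        )
    return total
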