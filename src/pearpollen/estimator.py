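"""Count-to-pollen conversion: reference pricing, Other-stage ratio rule,
multi-image aggregation and the occlusion correction.

The estimate for one image or branch is

    total (mg) = Σ_stage  n_stage × unit_mass(stage)

where the unit mass comes from the variety's reference table (raw or
effective mode).  ``TOO_LATE`` contributes 0 by definition.  ``OTHER``
flowers — side/back views indistinguishable between ``LATE`` and
``TOO_LATE`` — are priced at the count-weighted mean of those two stages'
unit masses in the same image:

    unit(OTHER) = n_late / (n_late + n_too_late) × unit(LATE)

Flowers hidden behind branches never appear in an image, so count-based
estimates are biased low; assuming flowers hidden over a 45°–90° angular
range, about 12.5–25% are invisible and the aggregate is corrected by a
scalar factor in [1.125, 1.25].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

from .reference import FloweringStage, PollenReference, StageCounts, _select_mode

__all__ = [
    "PollenEstimate",
    "other_stage_unit_pollen",
    "estimate_pollen",
    "apply_occlusion_correction",
    "aggregate_estimates",
    "DEFAULT_CORRECTION_FACTOR",
    "CORRECTION_FACTOR_RANGE",
]

#: Occlusion-correction band implied by the 45°–90° hidden-angle assumption.
CORRECTION_FACTOR_RANGE = (1.125, 1.25)
#: Midpoint of the band, used when correction is requested without a factor.
DEFAULT_CORRECTION_FACTOR = 1.1875


@dataclass(frozen=True)
class PollenEstimate:
    """Pollen-mass estimate for a set of counted flowers.

    ``per_stage_mg`` maps each stage to its mass contribution;
    ``other_unit_mg`` is the per-flower mass used for OTHER.
    ``other_fallback`` flags the degenerate case where OTHER flowers were
    present but no LATE/TOO_LATE flowers existed to set their price.
    """

    variety: str
    mode: str
    counts: StageCounts
    per_stage_mg: Mapping[FloweringStage, float]
    other_unit_mg: float
    total_mg: float
    correction_factor: float = 1.0
    corrected_total_mg: Optional[float] = None
    other_fallback: bool = False


def other_stage_unit_pollen(
    n_late: int,
    n_too_late: int,
    reference: PollenReference,
    mode: str = "raw",
) -> tuple[float, bool]:
    """Per-flower mass (mg) for OTHER flowers, plus a degenerate-case flag.

    Count-weighted mean of the LATE and TOO_LATE unit masses; since
    TOO_LATE is 0 this reduces to ``n_late/(n_late+n_too_late) × p_late``.
    With no LATE or TOO_LATE flowers at all the ratio is undefined and the
    fallback ``p_late / 2`` is returned with the flag set.
    """
    if n_late < 0 or n_too_late < 0:
        raise ValueError("counts must be non-negative")
    p_late = reference.unit_mass(FloweringStage.LATE, mode)
    p_too_late = reference.unit_mass(FloweringStage.TOO_LATE, mode)
    denom = n_late + n_too_late
    if denom == 0:
        return p_late / 2, True
    return (n_late * p_late + n_too_late * p_too_late) / denom, False


def estimate_pollen(
    counts: StageCounts,
    reference: PollenReference,
    mode: str = "raw",
) -> PollenEstimate:
    """Convert per-stage counts to a pollen-mass estimate (mg).

    ``mode`` selects the raw per-flower column or the fruiting-rate-discounted
    effective column.
    """
    _select_mode(reference, mode)  # validate mode early
    other_unit, fallback = other_stage_unit_pollen(
        counts[FloweringStage.LATE], counts[FloweringStage.TOO_LATE],
        reference, mode,
    )
    per_stage: dict[FloweringStage, float] = {}
    for stage in FloweringStage:
        if stage is FloweringStage.OTHER:
            unit = other_unit
        else:
            unit = reference.unit_mass(stage, mode)
        per_stage[stage] = counts[stage] * unit
    return PollenEstimate(
        variety=reference.variety,
        mode=mode,
        counts=counts,
        per_stage_mg=per_stage,
        other_unit_mg=other_unit,
        total_mg=sum(per_stage.values()),
        other_fallback=fallback and counts[FloweringStage.OTHER] > 0,
    )


def apply_occlusion_correction(
    estimate: PollenEstimate, factor: Optional[float] = None
) -> PollenEstimate:
    """Inflate the aggregate estimate by an occlusion factor ≥ 1.

    Only the total is corrected; per-stage contributions describe what was
    actually seen and are left untouched.  Default factor 1.1875, the
    midpoint of the 1.125–1.25 band.
    """
    if factor is None:
        factor = DEFAULT_CORRECTION_FACTOR
    if factor < 1.0:
        raise ValueError(
            f"occlusion factor must be >= 1 (occlusion only hides flowers), got {factor}"
        )
    return replace(
        estimate,
        correction_factor=factor,
        corrected_total_mg=estimate.total_mg * factor,
    )


def aggregate_estimates(
    estimates: Sequence[PollenEstimate],
    reference: Optional[PollenReference] = None,
) -> PollenEstimate:
    """Pool per-image estimates into one (e.g. whole-tree from many photos).

    Counts are summed and the estimate recomputed on the pooled counts, so the
    OTHER unit mass is re-priced from the pooled LATE/TOO_LATE ratio.  All
    inputs must share one variety and mode.  Pass ``reference`` explicitly,
    or leave it ``None`` to reload the packaged table for the shared variety.
    """
    estimates = list(estimates)
    if not estimates:
        if reference is None:
            raise ValueError("cannot aggregate an empty sequence without a reference")
        return estimate_pollen(StageCounts({}), reference)
    varieties = {e.variety for e in estimates}
    modes = {e.mode for e in estimates}
    if len(varieties) > 1 or len(modes) > 1:
        raise ValueError(
            f"cannot aggregate mixed estimates: varieties={sorted(varieties)}, "
            f"modes={sorted(modes)}"
        )
    if reference is None:
        from .reference import load_reference

        reference = load_reference(estimates[0].variety)
    elif reference.variety != estimates[0].variety:
        raise ValueError(
            f"reference variety {reference.variety!r} does not match "
            f"estimates ({estimates[0].variety!r})"
        )
    pooled = StageCounts({})
    for est in estimates:
        pooled = pooled + est.counts
    return estimate_pollen(pooled, reference, estimates[0].mode)
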