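"""Flowering-stage vocabulary and per-variety pollen reference tables.

Pear flowers are scored into five morphological stages between bud and
post-bloom:

* ``EARLY`` — immature bud;
* ``BEST`` — balloon-shaped bud, the stage of maximal collectable pollen;
* ``LATE`` — open bloom with red anthers;
* ``TOO_LATE`` — post-bloom, anthers dark, pollen already burst (zero
  collectable pollen by definition);
* ``OTHER`` — side or back views where ``LATE`` and ``TOO_LATE`` cannot be
  told apart.

A :class:`PollenReference` holds, per variety, the measured pollen mass per
flower for the four unambiguous stages (mg/flower), both raw and discounted
by the stage's fruiting rate ("effective" pollen).  ``OTHER`` carries no
static entry: its unit mass is priced per image from the observed ratio of
``LATE`` to ``TOO_LATE`` flowers (see :mod:`pearpollen.estimator`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

__all__ = [
    "FloweringStage",
    "STAGE_LABELS",
    "PollenReference",
    "StageCounts",
    "ReferenceError",
    "load_reference",
    "load_reference_table",
    "write_reference_table",
    "list_varieties",
    "fruiting_rate",
]


class ReferenceError(ValueError):
    """Raised for unknown varieties or invariant-violating tables."""


class FloweringStage(enum.IntEnum):
    """The five flowering-stage labels, in detector class-index order."""

    EARLY = 0
    BEST = 1
    LATE = 2
    TOO_LATE = 3
    OTHER = 4

    @property
    def class_index(self) -> int:
        return int(self)

    @property
    def label(self) -> str:
        return STAGE_LABELS[self]


#: Human-readable labels, as used in reference-table files.
STAGE_LABELS: Mapping[FloweringStage, str] = {
    FloweringStage.EARLY: "Early",
    FloweringStage.BEST: "Best",
    FloweringStage.LATE: "Late",
    FloweringStage.TOO_LATE: "Too late",
    FloweringStage.OTHER: "Other",
}

_LABEL_TO_STAGE = {v: k for k, v in STAGE_LABELS.items()}

#: Stages with a static per-flower entry in a reference table.
TABLE_STAGES = (
    FloweringStage.EARLY,
    FloweringStage.BEST,
    FloweringStage.LATE,
    FloweringStage.TOO_LATE,
)


def stage_from_label(label: str) -> FloweringStage:
    try:
        return _LABEL_TO_STAGE[label]
    except KeyError:
        raise ReferenceError(
            f"unknown stage label {label!r}; expected one of "
            f"{sorted(_LABEL_TO_STAGE)}"
        ) from None


@dataclass(frozen=True)
class PollenReference:
    """Per-variety, per-stage pollen mass per flower (mg).

    ``per_flower_mg`` is the raw measured mass; ``effective_mg`` is that mass
    multiplied by the stage's fruiting rate (the probability that artificial
    pollination with pollen from that stage sets fruit), so effective ≤ raw
    cell-wise.  ``sd_per_flower`` stores the published per-stage standard
    deviations as opaque values; their units are not stated consistently with
    the mg-scale means, so no computation uses them by default.
    """

    variety: str
    per_flower_mg: Mapping[FloweringStage, float]
    effective_mg: Mapping[FloweringStage, float]
    sd_per_flower: Optional[Mapping[FloweringStage, float]] = None

    def __post_init__(self) -> None:
        for name, table in (
            ("per_flower_mg", self.per_flower_mg),
            ("effective_mg", self.effective_mg),
        ):
            missing = [s.label for s in TABLE_STAGES if s not in table]
            if missing:
                raise ReferenceError(
                    f"{self.variety}: {name} is missing stages {missing}"
                )
            for stage in TABLE_STAGES:
                if table[stage] < 0:
                    raise ReferenceError(
                        f"{self.variety}: {name}[{stage.label}] is negative"
                    )
        for table in (self.per_flower_mg, self.effective_mg):
            if FloweringStage.OTHER in table:
                raise ReferenceError(
                    f"{self.variety}: OTHER has no static reference entry; "
                    "it is priced per image from the Late/Too-late ratio"
                )
        if self.per_flower_mg[FloweringStage.TOO_LATE] != 0:
            raise ReferenceError(
                f"{self.variety}: Too late must have zero per-flower pollen"
            )
        if self.effective_mg[FloweringStage.TOO_LATE] != 0:
            raise ReferenceError(
                f"{self.variety}: Too late must have zero effective pollen"
            )
        for stage in TABLE_STAGES:
            if self.effective_mg[stage] > self.per_flower_mg[stage] + 1e-12:
                raise ReferenceError(
                    f"{self.variety}: effective_mg[{stage.label}] exceeds "
                    "per_flower_mg (fruiting rate would exceed 1)"
                )

    def unit_mass(self, stage: FloweringStage, mode: str = "raw") -> float:
        """Per-flower mass (mg) for a table stage in ``raw`` or ``effective`` mode."""
        table = _select_mode(self, mode)
        if stage not in table:
            raise ReferenceError(
                f"{stage.label} has no static reference entry for {self.variety}"
            )
        return float(table[stage])


def _select_mode(reference: PollenReference, mode: str):
    if mode == "raw":
        return reference.per_flower_mg
    if mode == "effective":
        return reference.effective_mg
    raise ReferenceError(f"mode must be 'raw' or 'effective', got {mode!r}")


def fruiting_rate(reference: PollenReference, stage: FloweringStage) -> float:
    """Fruit-set probability for *stage* = effective mass / raw mass.

    Undefined for stages with zero raw pollen (``TOO_LATE``).
    """
    raw = reference.unit_mass(stage, "raw")
    if raw <= 0:
        raise ReferenceError(
            f"fruiting rate undefined for {stage.label}: zero raw pollen"
        )
    return reference.unit_mass(stage, "effective") / raw


@dataclass(frozen=True)
class StageCounts:
    """Non-negative per-stage flower counts for one image or branch."""

    counts: Mapping[FloweringStage, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {s: int(self.counts.get(s, 0)) for s in FloweringStage}
        for stage, n in full.items():
            if n < 0:
                raise ValueError(f"negative count for {stage.label}: {n}")
        object.__setattr__(self, "counts", full)

    @classmethod
    def from_sequence(cls, values: Iterable[int]) -> "StageCounts":
        """Build from five integers in class-index order (Early..Other)."""
        vals = list(values)
        if len(vals) != 5:
            raise ValueError(f"expected 5 counts, got {len(vals)}")
        return cls(dict(zip(FloweringStage, vals)))

    def __getitem__(self, stage: FloweringStage) -> int:
        return self.counts[stage]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "StageCounts") -> "StageCounts":
        return StageCounts(
            {s: self.counts[s] + other.counts[s] for s in FloweringStage}
        )


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ["variety", "stage", "per_flower_mg", "effective_mg"]


def _packaged_table_path() -> Path:
    return Path(resources.files("pearpollen").joinpath("data/pollen_reference.csv"))


def load_reference_table(path: Union[str, Path, None] = None) -> dict[str, PollenReference]:
    """Load every variety from a reference CSV (packaged table by default).

    The file format is comma-separated with header columns
    ``variety,stage,per_flower_mg,effective_mg`` and stage names spelled
    exactly ``Early``, ``Best``, ``Late``, ``Too late`` (``Other`` rows are
    rejected — it has no static entry).
    """
    table_path = _packaged_table_path() if path is None else Path(path)
    frame = pd.read_csv(table_path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ReferenceError(
            f"{table_path}: missing required columns {missing}; "
            f"expected header {','.join(_REQUIRED_COLUMNS)}"
        )
    references: dict[str, PollenReference] = {}
    for variety, group in frame.groupby("variety", sort=False):
        per_flower: dict[FloweringStage, float] = {}
        effective: dict[FloweringStage, float] = {}
        for row in group.itertuples(index=False):
            stage = stage_from_label(str(row.stage))
            if stage is FloweringStage.OTHER:
                raise ReferenceError(
                    f"{table_path}: 'Other' may not appear in a reference table"
                )
            per_flower[stage] = float(row.per_flower_mg)
            effective[stage] = float(row.effective_mg)
        references[str(variety)] = PollenReference(
            variety=str(variety), per_flower_mg=per_flower, effective_mg=effective
        )
    return references


def write_reference_table(
    references: Iterable[PollenReference], path: Union[str, Path]
) -> None:
    """Write references to CSV in the documented format (round-trips losslessly)."""
    rows = [
        {
            "variety": ref.variety,
            "stage": stage.label,
            "per_flower_mg": ref.per_flower_mg[stage],
            "effective_mg": ref.effective_mg[stage],
        }
        for ref in references
        for stage in TABLE_STAGES
    ]
    pd.DataFrame(rows, columns=_REQUIRED_COLUMNS).to_csv(path, index=False)


def list_varieties(path: Union[str, Path, None] = None) -> list[str]:
    return sorted(load_reference_table(path))


def load_reference(
    variety: str, path: Union[str, Path, None] = None
) -> PollenReference:
    """Load one variety's validated reference (packaged: Chojuro, Shinko, Nepal)."""
    table = load_reference_table(path)
    try:
        return table[variety]
    except KeyError:
        raise ReferenceError(
            f"unknown variety {variety!r}; available: {', '.join(sorted(table))}"
        ) from None
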