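"""Domain types and tabular I/O for trait questionnaires and EMA eating-event diaries.

The data model mirrors a common EMA study design: each participant fills in a
one-shot trait questionnaire rating each eating motive on a 4-point Likert
scale ("why I usually eat what I eat"), and then logs eating occasions over a
diary period, rating the same motives in the moment of eating ("why I am
eating right now").  Fifteen motives from The Eating Motivation Survey (TEMS)
form the default profile axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "TEMS_MOTIVES",
    "MEAL_TYPES",
    "MotiveCatalog",
    "LikertScale",
    "TraitProfile",
    "EatingEvent",
    "CohortDataset",
    "SchemaError",
    "read_cohort",
    "write_cohort",
]

#: The 15 basic TEMS motives, in the canonical survey order.
TEMS_MOTIVES: tuple[str, ...] = (
    "liking",
    "habit",
    "need_and_hunger",
    "health",
    "convenience",
    "pleasure",
    "traditional_eating",
    "natural_concerns",
    "sociability",
    "price",
    "visual_appeal",
    "weight_control",
    "affect_regulation",
    "social_norms",
    "social_image",
)

#: Closed set of meal categories for a logged eating occasion.
MEAL_TYPES: tuple[str, ...] = ("breakfast", "lunch", "afternoon_tea", "snack", "dinner")


class SchemaError(ValueError):
    """A located validation failure in tabular input.

    Carries ``row`` (0-based data-row index, or None for file-level problems)
    and ``column`` so callers can point users at the offending cell.
    """

    def __init__(self, message: str, *, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        super().__init__(message + (f" ({', '.join(loc)})" if loc else ""))
        self.row = row
        self.column = column


@dataclass(frozen=True)
class MotiveCatalog:
    """Ordered set of the 15 motive identifiers; the profile axis everywhere."""

    motives: tuple[str, ...] = TEMS_MOTIVES

    def __post_init__(self) -> None:
        object.__setattr__(self, "motives", tuple(self.motives))
        if len(self.motives) != 15:
            raise ValueError(f"catalog must contain exactly 15 motives, got {len(self.motives)}")
        if len(set(self.motives)) != len(self.motives):
            raise ValueError("catalog motives must be unique")

    def __len__(self) -> int:
        return len(self.motives)

    def __iter__(self):
        return iter(self.motives)

    def index(self, motive: str) -> int:
        return self.motives.index(motive)


@dataclass(frozen=True)
class LikertScale:
    """Bounds of the rating scale, inclusive. Default 1 ("strongly disagree") .. 4 ("strongly agree")."""

    min_value: float = 1.0
    max_value: float = 4.0

    def __post_init__(self) -> None:
        if not self.min_value < self.max_value:
            raise ValueError("scale requires min_value < max_value")

    @property
    def range(self) -> float:
        return self.max_value - self.min_value

    def contains(self, value: float) -> bool:
        return self.min_value <= value <= self.max_value


def _check_ratings(
    ratings: Mapping[str, float],
    catalog: MotiveCatalog,
    scale: LikertScale,
    *,
    strict_integer: bool,
    row: int | None = None,
) -> None:
    for motive in catalog:
        if motive not in ratings:
            raise SchemaError(f"missing rating for motive {motive!r}", row=row, column=motive)
        v = ratings[motive]
        if not isinstance(v, (int, float)) or v != v:  # NaN check
            raise SchemaError(f"rating for {motive!r} is not a number: {v!r}", row=row, column=motive)
        if not scale.contains(float(v)):
            raise SchemaError(
                f"rating {v} for {motive!r} outside scale [{scale.min_value}, {scale.max_value}]",
                row=row,
                column=motive,
            )
        if strict_integer and float(v) != int(v):
            raise SchemaError(f"rating {v} for {motive!r} is not an integer", row=row, column=motive)
    extra = set(ratings) - set(catalog.motives)
    if extra:
        raise SchemaError(f"unknown motives in ratings: {sorted(extra)}", row=row)


@dataclass(frozen=True)
class TraitProfile:
    """One participant's dispositional motive ratings."""

    participant_id: str
    ratings: Mapping[str, float]

    def vector(self, catalog: MotiveCatalog) -> list[float]:
        return [float(self.ratings[m]) for m in catalog]


@dataclass(frozen=True)
class EatingEvent:
    """One logged eating occasion with in-the-moment (state) motive ratings."""

    participant_id: str
    day_index: int
    meal_type: str
    ratings: Mapping[str, float]

    def vector(self, catalog: MotiveCatalog) -> list[float]:
        return [float(self.ratings[m]) for m in catalog]


@dataclass
class CohortDataset:
    """A matched trait questionnaire table and EMA event table for one cohort."""

    traits: list[TraitProfile]
    events: list[EatingEvent]
    catalog: MotiveCatalog = field(default_factory=MotiveCatalog)
    scale: LikertScale = field(default_factory=LikertScale)
    provenance: str = "observed"

    def validate(self, *, strict_integer: bool = True) -> "CohortDataset":
        """Check every invariant; returns self so calls can be chained.

        ``strict_integer`` restricts raw ratings to whole numbers (the scale
        is discrete); derived/averaged profiles are validated with it off.
        """
        ids = [t.participant_id for t in self.traits]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate participant_id in traits")
        known = set(ids)
        for i, t in enumerate(self.traits):
            _check_ratings(t.ratings, self.catalog, self.scale, strict_integer=strict_integer, row=i)
        for i, e in enumerate(self.events):
            if e.participant_id not in known:
                raise SchemaError(
                    f"event references unknown participant {e.participant_id!r}",
                    row=i,
                    column="participant_id",
                )
            if e.meal_type not in MEAL_TYPES:
                raise SchemaError(f"unknown meal type {e.meal_type!r}", row=i, column="meal_type")
            if int(e.day_index) < 1:
                raise SchemaError(f"day_index must be >= 1, got {e.day_index}", row=i, column="day_index")
            _check_ratings(e.ratings, self.catalog, self.scale, strict_integer=strict_integer, row=i)
        return self

    @property
    def participant_ids(self) -> list[str]:
        return [t.participant_id for t in self.traits]

    def events_for(self, participant_id: str) -> list[EatingEvent]:
        return [e for e in self.events if e.participant_id == participant_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortDataset):
            return NotImplemented
        return (
            self.catalog == other.catalog
            and self.scale == other.scale
            and [(t.participant_id, t.vector(self.catalog)) for t in self.traits]
            == [(t.participant_id, t.vector(other.catalog)) for t in other.traits]
            and [(e.participant_id, e.day_index, e.meal_type, e.vector(self.catalog)) for e in self.events]
            == [(e.participant_id, e.day_index, e.meal_type, e.vector(other.catalog)) for e in other.events]
        )


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_cohort(
    trait_path: str | Path,
    event_path: str | Path,
    *,
    catalog: MotiveCatalog | None = None,
    scale: LikertScale | None = None,
    strict_integer: bool = True,
    provenance: str = "observed",
) -> CohortDataset:
    """Read and validate a cohort from two CSV files.

    ``traits.csv``: participant_id, then one column per catalog motive.
    ``events.csv``: participant_id, day_index, meal_type, then motive columns.
    """
    catalog = catalog or MotiveCatalog()
    scale = scale or LikertScale()
    tdf = pd.read_csv(trait_path, dtype={"participant_id": str})
    edf = pd.read_csv(event_path, dtype={"participant_id": str})
    _require_columns(tdf, ["participant_id", *catalog.motives], str(trait_path))
    _require_columns(edf, ["participant_id", "day_index", "meal_type", *catalog.motives], str(event_path))

    traits = [
        TraitProfile(
            participant_id=str(r["participant_id"]),
            ratings={m: float(r[m]) for m in catalog},
        )
        for r in tdf.to_dict("records")
    ]
    events = [
        EatingEvent(
            participant_id=str(r["participant_id"]),
            day_index=int(r["day_index"]),
            meal_type=str(r["meal_type"]),
            ratings={m: float(r[m]) for m in catalog},
        )
        for r in edf.to_dict("records")
    ]
    ds = CohortDataset(traits=traits, events=events, catalog=catalog, scale=scale, provenance=provenance)
    return ds.validate(strict_integer=strict_integer)


def write_cohort(dataset: CohortDataset, trait_path: str | Path, event_path: str | Path) -> None:
    """Write a cohort to the two-CSV layout read by :func:`read_cohort`."""
    cat = dataset.catalog

    def _num(v: float):
        f = float(v)
        return int(f) if f == int(f) else f

    tdf = pd.DataFrame(
        [{"participant_id": t.participant_id, **{m: _num(t.ratings[m]) for m in cat}} for t in dataset.traits],
        columns=["participant_id", *cat.motives],
    )
    edf = pd.DataFrame(
        [
            {
                "participant_id": e.participant_id,
                "day_index": e.day_index,
                "meal_type": e.meal_type,
                **{m: _num(e.ratings[m]) for m in cat},
            }
            for e in dataset.events
        ],
        columns=["participant_id", "day_index", "meal_type", *cat.motives],
    )
    tdf.to_csv(trait_path, index=False)
    edf.to_csv(event_path, index=False)
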