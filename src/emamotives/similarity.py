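"""Profile-similarity indices for a trait/state motive profile pair.

Two profiles over the same k motives are compared on four components:

* overall fit — the double-entry intraclass correlation ``ICC_de``, the
  Pearson correlation over the doubled pairing {(x_i, y_i)} ∪ {(y_i, x_i)}.
  With m the grand mean of all 2k values it has the closed form

      ICC_de = Σ (x_i - m)(y_i - m) / ( [Σ (x_i - m)^2 + Σ (y_i - m)^2] / 2 )

  and is sensitive to shape, scatter and elevation simultaneously;
* shape — the ordinary Pearson correlation r between the two vectors;
* scatter — Var_D, the raw difference of profile variances (trait − state,
  sample variance with n−1 denominator);
* elevation — M_D, the raw difference of profile means (trait − state).

Degenerate inputs (zero-variance profiles) yield NaN, never an exception, so
batch within-person analysis does not abort on one flat profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aggregate import StateSummary
from .data import MotiveCatalog, TraitProfile

__all__ = [
    "ProfilePair",
    "SimilarityIndices",
    "icc_double_entry",
    "shape_similarity",
    "scatter_similarity",
    "elevation_similarity",
    "similarity_profile",
    "between_person_pair",
    "within_person_pairs",
    "similarity_frame",
]


@dataclass(frozen=True)
class ProfilePair:
    """A trait vector and a state vector over the same motives, in catalog order."""

    trait: tuple[float, ...]
    state: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "trait", tuple(float(v) for v in self.trait))
        object.__setattr__(self, "state", tuple(float(v) for v in self.state))
        if len(self.trait) != len(self.state):
            raise ValueError("trait and state profiles must have equal length")
        if len(self.trait) == 0:
            raise ValueError("profiles must be non-empty")

    def __len__(self) -> int:
        return len(self.trait)


@dataclass(frozen=True)
class SimilarityIndices:
    """The four indices for one pair, plus ICC_de^2 as % variance explained."""

    icc_de: float
    shape_r: float
    scatter_var_d: float
    elevation_m_d: float
    variance_explained_pct: float
    label: str = ""


def icc_double_entry(pair: ProfilePair) -> float:
    """Double-entry intraclass correlation of the two profiles.

    NaN when both profiles are constant at the same value (zero denominator).
    """
    x = np.asarray(pair.trait, dtype=float)
    y = np.asarray(pair.state, dtype=float)
    if x.size < 2:
        raise ValueError("ICC_de needs profiles of length >= 2")
    m = (x.sum() + y.sum()) / (2 * x.size)
    num = float(((x - m) * (y - m)).sum())
    den = float((((x - m) ** 2).sum() + ((y - m) ** 2).sum()) / 2.0)
    if den == 0.0:
        return math.nan
    return num / den


def shape_similarity(pair: ProfilePair) -> float:
    """Pearson correlation between the two profiles; NaN if either is constant."""
    x = np.asarray(pair.trait, dtype=float)
    y = np.asarray(pair.state, dtype=float)
    if x.size < 2:
        raise ValueError("shape similarity needs profiles of length >= 2")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def scatter_similarity(pair: ProfilePair) -> float:
    """Var_D: sample variance(trait) − sample variance(state)."""
    x = np.asarray(pair.trait, dtype=float)
    y = np.asarray(pair.state, dtype=float)
    if x.size < 2:
        raise ValueError("scatter similarity needs profiles of length >= 2")
    return float(x.var(ddof=1) - y.var(ddof=1))


def elevation_similarity(pair: ProfilePair) -> float:
    """M_D: mean(trait) − mean(state)."""
    x = np.asarray(pair.trait, dtype=float)
    y = np.asarray(pair.state, dtype=float)
    return float(x.mean() - y.mean())


def variance_explained_pct(icc_de: float) -> float:
    """ICC_de squared, on the percentage scale."""
    return icc_de * icc_de * 100.0


def similarity_profile(pair: ProfilePair) -> SimilarityIndices:
    """All four indices for one pair; NaN components propagate independently."""
    icc = icc_double_entry(pair)
    return SimilarityIndices(
        icc_de=icc,
        shape_r=shape_similarity(pair),
        scatter_var_d=scatter_similarity(pair),
        elevation_m_d=elevation_similarity(pair),
        variance_explained_pct=variance_explained_pct(icc) if icc == icc else math.nan,
        label=pair.label,
    )


def _matched(traits: Sequence[TraitProfile], summaries: Sequence[StateSummary]):
    by_pid = {s.participant_id: s for s in summaries}
    return [(t, by_pid[t.participant_id]) for t in traits if t.participant_id in by_pid]


def between_person_pair(
    traits: Sequence[TraitProfile],
    summaries: Sequence[StateSummary],
    catalog: MotiveCatalog | None = None,
) -> ProfilePair:
    """Group-level pair: per-motive means across participants.

    Each participant contributes equally — the state side averages person
    means, not pooled events — so logging frequency does not reweight the
    group profile.
    """
    catalog = catalog or MotiveCatalog()
    matched = _matched(traits, summaries)
    if not matched:
        raise ValueError("no participant appears in both traits and state summaries")
    tmat = np.array([t.vector(catalog) for t, _ in matched])
    smat = np.array([[s.state_mean[m] for m in catalog] for _, s in matched])
    return ProfilePair(trait=tuple(tmat.mean(axis=0)), state=tuple(smat.mean(axis=0)), label="group")


def within_person_pairs(
    traits: Sequence[TraitProfile],
    summaries: Sequence[StateSummary],
    catalog: MotiveCatalog | None = None,
) -> tuple[list[tuple[str, ProfilePair]], list[str]]:
    """One (participant_id, pair) per matched participant, in traits order.

    Participants without a state summary (below the event threshold) are
    returned in the second element as an exclusion report.
    """
    catalog = catalog or MotiveCatalog()
    have = {s.participant_id for s in summaries}
    excluded = [t.participant_id for t in traits if t.participant_id not in have]
    pairs = [
        (
            t.participant_id,
            ProfilePair(
                trait=tuple(t.vector(catalog)),
                state=tuple(s.state_mean[m] for m in catalog),
                label=t.participant_id,
            ),
        )
        for t, s in _matched(traits, summaries)
    ]
    return pairs, excluded


def similarity_frame(
    group: SimilarityIndices, per_person: Iterable[tuple[str, SimilarityIndices]]
) -> pd.DataFrame:
    """Long table of indices: one group row followed by one row per participant."""
    rows = [
        {
            "level": "group",
            "label": "group",
            "icc_de": group.icc_de,
            "shape_r": group.shape_r,
            "scatter_var_d": group.scatter_var_d,
            "elevation_m_d": group.elevation_m_d,
            "variance_explained_pct": group.variance_explained_pct,
        }
    ]
    for pid, s in per_person:
        rows.append(
            {
                "level": "participant",
                "label": pid,
                "icc_de": s.icc_de,
                "shape_r": s.shape_r,
                "scatter_var_d": s.scatter_var_d,
                "elevation_m_d": s.elevation_m_d,
                "variance_explained_pct": s.variance_explained_pct,
            }
        )
    return pd.DataFrame(rows)
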