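"""Collapse event-level state ratings to person-level profiles; occasion summaries.

State motives are averaged (unweighted) across all of a participant's eating
occasions; per-motive sample variances (n-1 denominator) quantify the
within-person fluctuation used for background shading in the matrix plot.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .data import MEAL_TYPES, CohortDataset

__all__ = ["StateSummary", "OccasionSummary", "summarize_states", "summarize_occasions", "shares_from_counts"]


@dataclass(frozen=True)
class StateSummary:
    """Per-participant state profile: mean and sample variance per motive across events.

    ``state_var`` values are NaN when the participant logged fewer than two
    events (a sample variance needs at least two points).
    """

    participant_id: str
    n_events: int
    state_mean: Mapping[str, float]
    state_var: Mapping[str, float]


@dataclass(frozen=True)
class OccasionSummary:
    """Meal-type counts and percentage shares over all logged occasions."""

    counts: Mapping[str, int]
    total: int
    shares: Mapping[str, float]


def summarize_states(
    dataset: CohortDataset, min_events: int = 1
) -> tuple[list[StateSummary], list[str]]:
    """Average each participant's state ratings across all their eating occasions.

    Returns ``(summaries, excluded)`` where ``excluded`` lists participants
    with fewer than ``min_events`` logged occasions — reported, never silently
    dropped.  Summaries follow the trait-table participant order.
    """
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    if not dataset.events:
        warnings.warn("dataset contains no events; returning empty state summaries", stacklevel=2)
    cat = list(dataset.catalog)
    by_pid: dict[str, list[list[float]]] = {pid: [] for pid in dataset.participant_ids}
    for e in dataset.events:
        by_pid[e.participant_id].append(e.vector(dataset.catalog))

    summaries: list[StateSummary] = []
    excluded: list[str] = []
    for pid in dataset.participant_ids:
        rows = np.asarray(by_pid[pid], dtype=float)
        n = len(rows)
        if n < min_events:
            excluded.append(pid)
            continue
        means = rows.mean(axis=0)
        if n >= 2:
            variances = rows.var(axis=0, ddof=1)
        else:
            variances = np.full(len(cat), np.nan)
        summaries.append(
            StateSummary(
                participant_id=pid,
                n_events=n,
                state_mean={m: float(means[j]) for j, m in enumerate(cat)},
                state_var={m: float(variances[j]) for j, m in enumerate(cat)},
            )
        )
    return summaries, excluded


def shares_from_counts(counts: Mapping[str, int]) -> OccasionSummary:
    """Percentage shares (one decimal) from meal-type counts."""
    full = {m: int(counts.get(m, 0)) for m in MEAL_TYPES}
    total = sum(full.values())
    if total == 0:
        shares = {m: math.nan for m in MEAL_TYPES}
    else:
        shares = {m: round(100.0 * c / total, 1) for m, c in full.items()}
    return OccasionSummary(counts=full, total=total, shares=shares)


def summarize_occasions(dataset: CohortDataset) -> OccasionSummary:
    """Count eating occasions per meal type over the whole cohort."""
    counts: dict[str, int] = {m: 0 for m in MEAL_TYPES}
    for e in dataset.events:
        counts[e.meal_type] += 1
    return shares_from_counts(counts)


def state_summaries_frame(summaries: list[StateSummary], catalog) -> pd.DataFrame:
    """One row per participant: n_events, then mean_<motive> and var_<motive> columns."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {"participant_id": s.participant_id, "n_events": s.n_events}
        for m in catalog:
            row[f"mean_{m}"] = s.state_mean[m]
        for m in catalog:
            row[f"var_{m}"] = s.state_var[m]
        rows.append(row)
    return pd.DataFrame(rows)
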