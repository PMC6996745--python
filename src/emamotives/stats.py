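"""Per-motive trait-vs-state comparisons: paired t tests, Cohen's d, correlations.

For each motive, participants' trait ratings are paired with their averaged
state ratings.  The standardized mean difference uses the averaged-SD
convention d_av = (M_trait − M_state) / ((SD_trait + SD_state) / 2), with the
change-score convention d_z = t / sqrt(n) available as an option.  Raw
two-sided p-values are primary; a Holm-adjusted column is emitted alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .aggregate import StateSummary
from .data import MotiveCatalog, TraitProfile

__all__ = [
    "MotiveComparison",
    "compare_motive",
    "compare_all_motives",
    "band_effect",
    "band_correlation",
    "comparisons_frame",
]

EFFECT_BANDS = ("negligible", "small", "moderate", "large")
R_BANDS = ("low", "medium", "high")


@dataclass(frozen=True)
class MotiveComparison:
    """Between-person statistics for one motive's trait/state contrast."""

    motive: str
    n: int
    trait_mean: float
    state_mean: float
    mean_diff: float
    trait_var: float
    state_var: float
    t_stat: float
    df: int
    p_value: float
    cohen_d: float
    trait_state_r: float
    effect_band: str | None
    r_band: str | None


def band_effect(d: float) -> str | None:
    """Descriptive band for |d|: >0.8 large, >0.5 moderate, >0.3 small, else negligible."""
    if d != d:
        return None
    a = abs(d)
    if a > 0.8:
        return "large"
    if a > 0.5:
        return "moderate"
    if a > 0.3:
        return "small"
    return "negligible"


def band_correlation(r: float) -> str | None:
    """Descriptive band for r: >=0.50 high, >0.30 medium, else low."""
    if r != r:
        return None
    if r >= 0.50:
        return "high"
    if r > 0.30:
        return "medium"
    return "low"


def compare_motive(
    motive: str,
    traits: Sequence[TraitProfile],
    summaries: Sequence[StateSummary],
    *,
    d_convention: str = "av",
) -> MotiveComparison:
    """Paired comparison of trait ratings vs. averaged state ratings for one motive.

    Degenerate inputs (zero variance of the paired differences, or zero
    between-person variance on both sides) yield NaN statistics rather than
    exceptions.  Fewer than three matched participants is an error here; the
    batch entry point :func:`compare_all_motives` degrades to NaN statistics
    instead so small cohorts still produce a full table.
    """
    n = len(_paired_values(motive, traits, summaries)[0])
    if n < 3:
        raise ValueError(f"need >= 3 matched participants for motive {motive!r}, got {n}")
    return _compare_lenient(motive, traits, summaries, d_convention=d_convention)


def _paired_values(motive, traits, summaries):
    by_pid = {s.participant_id: s for s in summaries}
    x, y = [], []
    for t in traits:
        s = by_pid.get(t.participant_id)
        if s is None:
            continue
        sm = s.state_mean[motive]
        if sm != sm:
            continue
        x.append(float(t.ratings[motive]))
        y.append(sm)
    return x, y


def _compare_lenient(
    motive: str,
    traits: Sequence[TraitProfile],
    summaries: Sequence[StateSummary],
    *,
    d_convention: str = "av",
) -> MotiveComparison:
    if d_convention not in ("av", "z"):
        raise ValueError("d_convention must be 'av' or 'z'")
    x, y = _paired_values(motive, traits, summaries)
    n = len(x)
    if n == 0:
        raise ValueError(f"no matched participants for motive {motive!r}")
    x_arr = np.asarray(x)
    y_arr = np.asarray(y)
    diff = x_arr - y_arr
    mean_diff = float(diff.mean())
    if n >= 2:
        sd_x = float(x_arr.std(ddof=1))
        sd_y = float(y_arr.std(ddof=1))
        sd_diff = float(diff.std(ddof=1))
    else:
        sd_x = sd_y = sd_diff = math.nan

    if n >= 3 and sd_diff > 0:
        t_res = sps.ttest_rel(x_arr, y_arr)
        t_stat, p_value = float(t_res.statistic), float(t_res.pvalue)
    else:
        t_stat, p_value = math.nan, math.nan

    if d_convention == "av":
        denom = (sd_x + sd_y) / 2.0
        cohen_d = mean_diff / denom if denom > 0 else math.nan
    else:
        cohen_d = t_stat / math.sqrt(n) if t_stat == t_stat else math.nan

    if n >= 3 and sd_x > 0 and sd_y > 0:
        r = float(sps.pearsonr(x_arr, y_arr).statistic)
    else:
        r = math.nan

    return MotiveComparison(
        motive=motive,
        n=n,
        trait_mean=float(x_arr.mean()),
        state_mean=float(y_arr.mean()),
        mean_diff=mean_diff,
        trait_var=sd_x**2,
        state_var=sd_y**2,
        t_stat=t_stat,
        df=n - 1,
        p_value=p_value,
        cohen_d=cohen_d,
        trait_state_r=r,
        effect_band=band_effect(cohen_d),
        r_band=band_correlation(r),
    )


def compare_all_motives(
    traits: Sequence[TraitProfile],
    summaries: Sequence[StateSummary],
    *,
    alpha: float = 0.05,
    catalog: MotiveCatalog | None = None,
    d_convention: str = "av",
) -> tuple[list[MotiveComparison], dict[str, int]]:
    """One comparison per catalog motive, plus overall counts.

    ``counts['overestimated']`` is the number of motives with p < alpha and
    a positive trait-minus-state mean difference — the motives the trait
    questionnaire overestimates.
    """
    catalog = catalog or MotiveCatalog()
    comparisons = [
        _compare_lenient(m, traits, summaries, d_convention=d_convention) for m in catalog
    ]
    n_sig = sum(1 for c in comparisons if c.p_value == c.p_value and c.p_value < alpha)
    n_over = sum(
        1
        for c in comparisons
        if c.p_value == c.p_value and c.p_value < alpha and c.mean_diff > 0
    )
    return comparisons, {"significant": n_sig, "overestimated": n_over}


def comparisons_frame(comparisons: Sequence[MotiveComparison]) -> pd.DataFrame:
    """Tabulate comparisons; adds a Holm-adjusted p column alongside raw p."""
    df = pd.DataFrame([c.__dict__ for c in comparisons])
    pvals = df["p_value"].to_numpy()
    ok = ~np.isnan(pvals)
    holm = np.full_like(pvals, np.nan)
    if ok.any():
        holm[ok] = multipletests(pvals[ok], method="holm")[1]
    df.insert(df.columns.get_loc("p_value") + 1, "p_holm", holm)
    return df
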