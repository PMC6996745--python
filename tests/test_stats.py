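"""Per-motive paired comparisons, effect sizes, and descriptive banding."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from emamotives import (
    MotiveCatalog,
    StateSummary,
    TraitProfile,
    band_correlation,
    band_effect,
    compare_all_motives,
    compare_motive,
)
from emamotives.stats import comparisons_frame
from tests.conftest import ratings

CAT = MotiveCatalog()


def _fixture(trait_vals, state_vals, motive="liking"):
    traits = [TraitProfile(f"P{i}", ratings(2, **{motive: v})) for i, v in enumerate(trait_vals)]
    summaries = [
        StateSummary(f"P{i}", 5, ratings(2, **{motive: v}), {m: 0.2 for m in CAT})
        for i, v in enumerate(state_vals)
    ]
    return traits, summaries


def paired_t_oracle(x, y):
    """Brute-force paired t: mean(d) * sqrt(n) / SD(d), two-sided p on n-1 df."""
    d = np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    t = d.mean() * math.sqrt(n) / d.std(ddof=1)
    p = 2 * sps.t.sf(abs(t), n - 1)
    return t, p


class TestCompareMotive:
    def test_matches_paired_t_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = rng.integers(4, 30)
            x = rng.uniform(1, 4, n).round(2)
            y = np.clip(x - rng.normal(0.3, 0.4, n), 1, 4).round(2)
            traits, summaries = _fixture(x, y)
            c = compare_motive("liking", traits, summaries)
            t, p = paired_t_oracle(x, y)
            assert c.t_stat == pytest.approx(t, abs=1e-9)
            assert c.p_value == pytest.approx(p, abs=1e-9)
            assert c.df == n - 1
            assert c.cohen_d == pytest.approx(
                (x.mean() - y.mean()) / ((x.std(ddof=1) + y.std(ddof=1)) / 2), abs=1e-9
            )
            assert c.trait_state_r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-9)

    def test_equal_trait_and_state_gives_zero_diff_and_zero_d(self):
        vals = (1, 2, 3, 4, 2)
        c = compare_motive("liking", *_fixture(vals, vals))
        assert c.mean_diff == 0.0
        assert math.isnan(c.t_stat)  # all differences identically zero
        assert c.cohen_d == 0.0

    def test_constant_nonzero_differences_leave_t_undefined(self):
        c = compare_motive("liking", *_fixture((2, 3, 4, 2, 3), (1, 2, 3, 1, 2)))
        assert c.mean_diff == pytest.approx(1.0)
        assert math.isnan(c.t_stat) and math.isnan(c.p_value)

    def test_zero_variance_on_both_sides_gives_undefined_markers(self):
        c = compare_motive("liking", *_fixture((2, 2, 2), (1, 1, 1)))
        assert math.isnan(c.cohen_d) and math.isnan(c.trait_state_r)
        assert c.effect_band is None and c.r_band is None

    def test_needs_three_matched_participants(self):
        with pytest.raises(ValueError, match=">= 3"):
            compare_motive("liking", *_fixture((1, 2), (1, 2)))

    def test_antisymmetry_under_trait_state_swap(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(1, 4, 12)
        y = rng.uniform(1, 4, 12)
        fwd = compare_motive("liking", *_fixture(x, y))
        rev = compare_motive("liking", *_fixture(y, x))
        assert rev.mean_diff == pytest.approx(-fwd.mean_diff, abs=1e-12)
        assert rev.t_stat == pytest.approx(-fwd.t_stat, abs=1e-9)
        assert rev.cohen_d == pytest.approx(-fwd.cohen_d, abs=1e-9)
        assert rev.trait_state_r == pytest.approx(fwd.trait_state_r, abs=1e-12)

    def test_dz_convention_is_t_over_sqrt_n(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(1, 4, 10)
        y = rng.uniform(1, 4, 10)
        c = compare_motive("liking", *_fixture(x, y), d_convention="z")
        assert c.cohen_d == pytest.approx(c.t_stat / math.sqrt(10), abs=1e-12)


class TestBanding:
    @pytest.mark.parametrize(
        "d,band",
        [
            (1.97, "large"),
            (0.81, "large"),
            (0.8, "moderate"),
            (0.55, "moderate"),
            (0.5, "small"),
            (0.31, "small"),
            (0.30, "negligible"),  # strict '>' at the boundary
            (-1.0, "large"),
            (float("nan"), None),
        ],
    )
    def test_effect_bands(self, d, band):
        assert band_effect(d) == band

    @pytest.mark.parametrize(
        "r,band",
        [(0.50, "high"), (0.6, "high"), (0.49, "medium"), (0.31, "medium"), (0.30, "low"), (-0.2, "low"), (float("nan"), None)],
    )
    def test_correlation_bands(self, r, band):
        assert band_correlation(r) == band


class TestCompareAllMotives:
    def test_one_row_per_catalog_motive(self, studylike_runs):
        res = studylike_runs[0]
        assert [c.motive for c in res.comparisons] == list(CAT)

    def test_counts_and_bands_consistent_with_rows(self, studylike_runs):
        res = studylike_runs[0]
        over = [c for c in res.comparisons if c.p_value == c.p_value and c.p_value < 0.05 and c.mean_diff > 0]
        assert res.counts["overestimated"] == len(over)
        for c in res.comparisons:
            assert c.effect_band == band_effect(c.cohen_d)
            assert c.r_band == band_correlation(c.trait_state_r)

    def test_holm_column_dominates_raw_p(self, studylike_runs):
        df = comparisons_frame(studylike_runs[0].comparisons)
        ok = df["p_value"].notna()
        assert (df.loc[ok, "p_holm"] >= df.loc[ok, "p_value"] - 1e-15).all()
        assert len(df) == 15

    def test_type_one_error_calibrated_under_null_generator(self):
        # Zero elevation bias with interior motive means (so discretization does
        # not shift observed means); per-motive rejection rate near alpha.
        import emamotives as em

        means = {m: mu for m, mu in zip(CAT, np.linspace(3.1, 1.9, 15))}
        rej = tot = 0
        for seed in range(200, 240):
            cfg = em.studylike_config(seed=seed, elevation_bias={}, motive_means=means)
            ds = em.simulate_cohort(cfg)
            summaries, _ = em.summarize_states(ds)
            comps, _ = compare_all_motives(ds.traits, summaries)
            for c in comps:
                tot += 1
                rej += bool(c.p_value == c.p_value and c.p_value < 0.05)
        assert tot == 600
        assert 0.02 <= rej / tot <= 0.08
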