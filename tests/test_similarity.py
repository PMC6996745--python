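"""The four profile-similarity indices and their level-specific constructors."""

import math

import numpy as np
import pytest

from emamotives import (
    MotiveCatalog,
    ProfilePair,
    StateSummary,
    TraitProfile,
    between_person_pair,
    elevation_similarity,
    icc_double_entry,
    scatter_similarity,
    shape_similarity,
    similarity_profile,
    within_person_pairs,
)
from tests.conftest import ratings

CAT = MotiveCatalog()


def doubled_pearson_icc(x, y):
    """Independent oracle: Pearson r over the doubled pairing {(x,y)} U {(y,x)}."""
    a = np.concatenate([x, y])
    b = np.concatenate([y, x])
    return float(np.corrcoef(a, b)[0, 1])


class TestIccDoubleEntry:
    def test_identical_profiles_give_one(self):
        assert icc_double_entry(ProfilePair((1, 2, 3), (1, 2, 3))) == pytest.approx(1.0)

    def test_reversed_profile_gives_minus_one(self):
        # grand mean 2; numerator -2, denominator 2
        assert icc_double_entry(ProfilePair((1, 2, 3), (3, 2, 1))) == pytest.approx(-1.0)

    def test_uniform_shift_closed_form(self):
        # x=(1,2,3,4), y=x+1: grand mean 3, numerator 4, denominator 6
        assert icc_double_entry(ProfilePair((1, 2, 3, 4), (2, 3, 4, 5))) == pytest.approx(2 / 3)

    def test_closed_form_matches_doubled_pearson_on_1000_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            x = rng.uniform(1, 4, 15)
            y = rng.uniform(1, 4, 15)
            assert icc_double_entry(ProfilePair(tuple(x), tuple(y))) == pytest.approx(
                doubled_pearson_icc(x, y), abs=1e-10
            )

    def test_both_profiles_constant_and_equal_is_undefined_not_an_error(self):
        assert math.isnan(icc_double_entry(ProfilePair((2, 2, 2), (2, 2, 2))))

    def test_strictly_decreasing_in_elevation_offset(self):
        x = np.array([1.0, 2.0, 3.0, 2.5, 1.5])
        vals = [icc_double_entry(ProfilePair(tuple(x), tuple(x + c))) for c in (0, 0.5, 1, 1.5, 2)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[0] == pytest.approx(1.0)

    def test_equals_pearson_when_means_and_variances_match(self):
        x = (1.0, 3.0, 2.0, 4.0, 2.5)
        y = (2.0, 4.0, 2.5, 1.0, 3.0)  # permutation: same mean and variance
        pair = ProfilePair(x, y)
        assert icc_double_entry(pair) == pytest.approx(shape_similarity(pair), abs=1e-12)

    def test_joint_affine_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.uniform(1, 4, 15), rng.uniform(1, 4, 15)
        base = similarity_profile(ProfilePair(tuple(x), tuple(y)))
        for a, b in ((2.0, 1.0), (0.5, -3.0)):
            mapped = similarity_profile(ProfilePair(tuple(a * x + b), tuple(a * y + b)))
            assert mapped.icc_de == pytest.approx(base.icc_de, abs=1e-10)
            assert mapped.shape_r == pytest.approx(base.shape_r, abs=1e-10)


class TestComponentIndices:
    def test_shape_ignores_elevation(self):
        x = (1.0, 2.5, 3.0, 2.0)
        assert shape_similarity(ProfilePair(x, tuple(v + 0.5 for v in x))) == pytest.approx(1.0)

    def test_shape_hand_computation(self):
        assert shape_similarity(ProfilePair((1, 2, 3, 4), (1, 3, 2, 4))) == pytest.approx(0.8)

    def test_shape_undefined_for_constant_profile(self):
        assert math.isnan(shape_similarity(ProfilePair((2, 2, 2), (1, 2, 3))))

    def test_scatter_hand_computation_and_antisymmetry(self):
        pair = ProfilePair((1, 3), (2, 2))
        assert scatter_similarity(pair) == pytest.approx(2.0)
        assert scatter_similarity(ProfilePair(pair.state, pair.trait)) == pytest.approx(-2.0)
        assert scatter_similarity(ProfilePair((1, 2, 3), (1, 2, 3))) == 0.0

    def test_elevation_recovers_exact_shift(self):
        x = (1.0, 2.0, 4.0)
        assert elevation_similarity(ProfilePair(tuple(v + 0.53 for v in x), x)) == pytest.approx(0.53)
        assert elevation_similarity(ProfilePair(x, x)) == 0.0

    def test_elevation_of_grand_mean_profiles(self):
        # Reference-study grand means: trait 2.41 vs state 1.88 -> M_D = 0.53.
        assert elevation_similarity(ProfilePair((2.41,), (1.88,))) == pytest.approx(0.53)


class TestSimilarityProfileBundle:
    def test_variance_explained_is_squared_icc_in_percent(self):
        rng = np.random.default_rng(5)
        x, y = rng.uniform(1, 4, 15), rng.uniform(1, 4, 15)
        s = similarity_profile(ProfilePair(tuple(x), tuple(y)))
        assert s.variance_explained_pct == pytest.approx(s.icc_de**2 * 100, abs=1e-9)

    def test_undefined_components_propagate_independently(self):
        s = similarity_profile(ProfilePair((2, 2, 2), (1, 2, 3)))
        assert math.isnan(s.shape_r)
        assert not math.isnan(s.icc_de)
        assert s.scatter_var_d == pytest.approx(-1.0)
        assert s.elevation_m_d == 0.0


def _summary(pid, mean_map, n_events=5):
    return StateSummary(pid, n_events, mean_map, {m: 0.1 for m in CAT})


class TestLevelConstructors:
    def test_single_participant_group_pair_is_their_own_profiles(self):
        t = TraitProfile("A", ratings(2, liking=4))
        s = _summary("A", ratings(1, liking=3))
        pair = between_person_pair([t], [s])
        assert pair.trait == tuple(t.vector(CAT))
        assert pair.state == tuple(float(s.state_mean[m]) for m in CAT)
        assert pair.label == "group"

    def test_group_trait_value_is_mean_across_participants(self):
        pair = between_person_pair(
            [TraitProfile("A", ratings(1)), TraitProfile("B", ratings(3))],
            [_summary("A", ratings(2)), _summary("B", ratings(2))],
        )
        assert pair.trait == tuple([2.0] * 15)

    def test_group_state_averages_person_means_not_pooled_events(self):
        # A logs 1 event at rating 1; B logs 3 events at rating 4.  Person-mean
        # averaging gives 2.5; pooled events would give 3.25.
        sa = _summary("A", ratings(1), n_events=1)
        sb = _summary("B", ratings(4), n_events=3)
        pair = between_person_pair(
            [TraitProfile("A", ratings(2)), TraitProfile("B", ratings(2))], [sa, sb]
        )
        pooled = (1 * 1 + 3 * 4) / 4
        assert pair.state[0] == pytest.approx(2.5)
        assert pair.state[0] != pytest.approx(pooled)

    def test_disjoint_participant_sets_is_an_error(self):
        with pytest.raises(ValueError, match="no participant"):
            between_person_pair([TraitProfile("A", ratings())], [_summary("Z", ratings())])

    def test_within_person_pairs_follow_trait_order_and_report_exclusions(self):
        traits = [TraitProfile(p, ratings(2)) for p in ("B", "A", "C")]
        summaries = [_summary("A", ratings(1)), _summary("B", ratings(3))]
        pairs, excluded = within_person_pairs(traits, summaries)
        assert [pid for pid, _ in pairs] == ["B", "A"]
        assert excluded == ["C"]

    def test_full_cohort_yields_one_pair_per_participant(self, studylike_runs):
        res = studylike_runs[0]
        assert len(res.per_person) == 35
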