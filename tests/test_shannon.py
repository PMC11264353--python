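"""Shannon information statistics and the ¹H_IS formula."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shannonhet import (
    InvalidInputError,
    PoolingMode,
    PopulationProfile,
    UndefinedEvennessError,
    UndefinedStatisticError,
    VariantProfile,
    evenness,
    his,
    his_from_profiles,
    his_prime,
    individual_shannon,
    mean_individual_shannon,
    population_shannon,
)

from conftest import random_population


class TestIndividualShannon:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"A": 1, "B": 1, "C": 1, "D": 1}, math.log(4)),
            ({"A": 7}, 0.0),
            # direct summation: -(0.75 ln 0.75 + 0.25 ln 0.25)
            ({"A": 3, "B": 1}, 0.5623351446188083),
        ],
    )
    def test_known_values(self, counts, expected):
        assert individual_shannon(VariantProfile("x", counts)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_empty_profile_rejected(self):
        with pytest.raises(InvalidInputError):
            VariantProfile("x", {})
        with pytest.raises(InvalidInputError):
            VariantProfile("x", {"A": 0.0})

    @given(
        counts=st.lists(
            st.floats(min_value=0.01, max_value=1e3), min_size=1, max_size=12
        )
    )
    @settings(deadline=None)
    def test_matches_brute_force_oracle(self, counts):
        """-sum p ln p computed by an explicit loop over proportions."""
        profile = VariantProfile("x", {f"v{i}": c for i, c in enumerate(counts)})
        total = sum(counts)
        expected = 0.0
        for c in counts:
            p = c / total
            expected -= p * math.log(p)
        assert individual_shannon(profile) == pytest.approx(expected, abs=1e-12)
        assert 0 <= individual_shannon(profile) <= math.log(len(counts)) + 1e-12


class TestPopulationLevel:
    def test_mean_individual_shannon(self, two_individual_population):
        # (0 + ln 2) / 2
        assert mean_individual_shannon(two_individual_population) == pytest.approx(
            math.log(2) / 2, abs=1e-12
        )

    def test_single_individual_is_identity(self):
        pop = PopulationProfile([VariantProfile("i", {"A": 3, "B": 1})])
        assert mean_individual_shannon(pop) == pytest.approx(
            individual_shannon(pop.profiles[0]), abs=1e-15
        )

    def test_population_shannon_mean_of_proportions(self):
        # {A:3,B:1} and {A:1,B:3} average to (0.5, 0.5)
        pop = PopulationProfile(
            [VariantProfile("a", {"A": 3, "B": 1}),
             VariantProfile("b", {"A": 1, "B": 3})]
        )
        assert population_shannon(pop) == pytest.approx(math.log(2), abs=1e-12)

    def test_disjoint_profiles(self):
        pop = PopulationProfile(
            [VariantProfile("a", {"A": 4}), VariantProfile("b", {"B": 4})]
        )
        assert population_shannon(pop) == pytest.approx(math.log(2), abs=1e-12)

    def test_monomorphic_population(self):
        pop = PopulationProfile(
            [VariantProfile("a", {"A": 4}), VariantProfile("b", {"A": 1})]
        )
        assert population_shannon(pop) == 0.0

    def test_pooling_modes_differ_under_unequal_depth(self):
        pop_mean = PopulationProfile(
            [VariantProfile("a", {"A": 90, "B": 10}),
             VariantProfile("b", {"A": 1, "B": 1})]
        )
        pop_pooled = PopulationProfile(
            pop_mean.profiles, PoolingMode.POOLED_COUNTS
        )
        p_mean = pop_mean.population_proportions()
        p_pooled = pop_pooled.population_proportions()
        assert p_mean["A"] == pytest.approx(0.7)
        assert p_pooled["A"] == pytest.approx(91 / 102)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25)
    def test_population_shannon_matches_oracle(self, seed):
        pop = random_population(np.random.default_rng(seed))
        props = pop.population_proportions()
        expected = -sum(p * math.log(p) for p in props.values() if p > 0)
        assert population_shannon(pop) == pytest.approx(expected, abs=1e-12)


class TestEvenness:
    def test_uniform_is_one(self):
        pop = PopulationProfile(
            [VariantProfile("a", {f"v{i}": 1 for i in range(5)})]
        )
        assert evenness(pop) == pytest.approx(1.0, abs=1e-12)

    def test_skewed(self):
        pop = PopulationProfile(
            [VariantProfile("a", {"a": 97, "b": 1, "c": 1, "d": 1})]
        )
        # oracle: H_S = -(0.97 ln 0.97 + 3*0.01 ln 0.01) = 0.16770; ln 4
        assert evenness(pop) == pytest.approx(0.1209704, abs=1e-6)

    def test_single_variant_undefined(self):
        pop = PopulationProfile([VariantProfile("a", {"A": 4})])
        with pytest.raises(UndefinedEvennessError):
            evenness(pop)


class TestHisFormula:
    def test_worked_examples(self):
        assert his_prime(0.69, 1, 2) == pytest.approx(-0.07, abs=1e-12)
        assert his_prime(0.69, 1, 5) == pytest.approx(0.86, abs=1e-12)
        assert his(0.69, 1, 5, 0.1).his == pytest.approx(0.086, abs=1e-12)

    def test_zero_population_information_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            his_prime(0.0, 0.0, 3)
        with pytest.raises(UndefinedStatisticError):
            his(0.5, 0.0, 3, 0.5)

    @given(
        h=st.floats(min_value=1e-3, max_value=5.0),
        ev=st.floats(min_value=1e-6, max_value=1.0),
        loci=st.integers(1, 20),
    )
    @settings(deadline=None)
    def test_equal_information_collapses_to_minus_evenness(self, h, ev, loci):
        """H-bar = H_S makes the bracket -((L+1) - L) = -1, so his = -EV."""
        result = his(h, h, loci, ev)
        assert result.his == pytest.approx(-ev, rel=1e-9)
        assert result.his == pytest.approx(result.his_prime * ev, abs=1e-12)

    def test_strictly_increasing_in_loci_when_deficit(self):
        grid = [his_prime(0.6, 1.0, L) for L in range(1, 15)]
        assert all(b > a for a, b in zip(grid, grid[1:]))

    def test_clamping(self):
        res = his(1.787, 2.371, 9, 0.746, clamp=True)
        assert res.his_raw == pytest.approx(1.091, abs=5e-4)
        assert res.clamped and res.his == 1.0
        raw = his(1.787, 2.371, 9, 0.746, clamp=False)
        assert not raw.clamped and raw.his == raw.his_raw

    def test_invalid_evenness(self):
        with pytest.raises(InvalidInputError):
            his(0.5, 1.0, 3, 0.0)
        with pytest.raises(InvalidInputError):
            his(0.5, 1.0, 3, 1.5)


class TestHisFromProfiles:
    def test_identical_heterozygotes(self):
        pop = PopulationProfile(
            [VariantProfile(f"i{k}", {"A": 2, "B": 2}) for k in range(2)]
        )
        res = his_from_profiles(pop, loci=1)
        assert res.his == pytest.approx(-1.0, abs=1e-12)

    def test_distinct_homozygotes(self):
        pop = PopulationProfile(
            [VariantProfile("a", {"A": 4}), VariantProfile("b", {"B": 4})]
        )
        res = his_from_profiles(pop, loci=1)
        assert res.his == pytest.approx(1.0, abs=1e-12)
        assert res.h_bar == 0.0

    def test_total_fixation_undefined(self):
        pop = PopulationProfile(
            [VariantProfile(f"i{k}", {"A": 4}) for k in range(3)]
        )
        with pytest.raises(UndefinedStatisticError):
            his_from_profiles(pop, loci=2)
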