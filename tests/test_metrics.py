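"""Metric suite: worked values, the decomposition identity, and distribution properties."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from demopair import (
    PopulationSnapshot,
    StableStructure,
    build_stationary_population,
    compute_all,
    five_year_deaths,
    lifespan_parity_ratio,
    make_pair,
    make_stable_population,
    mean_age,
    mean_years_remaining,
    net_structural_aging,
    oadr,
    pct_over_65,
    stationarity_gap,
    structural_gap,
    survival_offset,
    terminal_dependency_ratio,
)
from demopair.errors import ComputationError, ValidationError
from demopair.lifetable import complete_life_table


def _pop(gm_table, counts):
    n = np.zeros(gm_table.omega + 1)
    for age, c in counts.items():
        n[age] = c
    return PopulationSnapshot(time=2020, n=n, lifetable=gm_table)


class TestConventionalMetrics:
    def test_all_mass_at_70_is_all_over_65(self, gm_table):
        assert pct_over_65(_pop(gm_table, {70: 5.0})) == pytest.approx(100.0)

    def test_uniform_counts_share_over_65(self, gm_table):
        pop = PopulationSnapshot(time=0, n=np.ones(101), lifetable=gm_table)
        assert pct_over_65(pop) == pytest.approx(100.0 * 36 / 101)

    def test_oadr_direct_ratio_and_percent_convention(self, gm_table):
        pop = _pop(gm_table, {30: 50.0, 70: 25.0})
        assert oadr(pop) == pytest.approx(0.5)
        assert oadr(pop, percent=True) == pytest.approx(50.0)

    def test_oadr_no_elderly_is_zero(self, gm_table):
        assert oadr(_pop(gm_table, {30: 10.0})) == 0.0

    def test_oadr_empty_denominator_is_an_error(self, gm_table):
        with pytest.raises(ComputationError):
            oadr(_pop(gm_table, {70: 10.0}))


class TestMeans:
    def test_point_mass(self, gm_table):
        assert mean_age(_pop(gm_table, {40: 9.0})) == pytest.approx(40.0)

    def test_weighted_mean_oracle(self, gm_table):
        pop = _pop(gm_table, {0: 2.0, 1: 1.0, 2: 1.0})
        assert mean_age(pop) == pytest.approx(0.75)
        assert mean_age(pop, midpoint=True) == pytest.approx(1.25)

    def test_single_cohort_remaining_is_expectancy(self, gm_table):
        pop = _pop(gm_table, {30: 11.0})
        assert mean_years_remaining(pop) == pytest.approx(gm_table.e[30])

    def test_survivorship_weighting_reproduces_stationary_value(self, gm_table, growing_pop):
        stationary = build_stationary_population(gm_table)
        assert mean_years_remaining(growing_pop, method="survivorship") == pytest.approx(
            mean_years_remaining(stationary, method="expectancy")
        )

    def test_lpr_is_ratio_of_matrix_mean_to_mean_age(self, growing_pop):
        expected = mean_years_remaining(growing_pop, method="matrix") / mean_age(growing_pop)
        assert lifespan_parity_ratio(growing_pop) == pytest.approx(expected, rel=1e-12)

    def test_lpr_unity_at_stationarity(self, stationary_pop):
        assert lifespan_parity_ratio(stationary_pop) == pytest.approx(1.0, abs=1e-9)


class TestStationarityGap:
    def test_identical_distributions(self):
        assert stationarity_gap(np.array([3.0, 1.0]), np.array([6.0, 2.0])) == 0.0

    def test_disjoint_supports_hit_the_maximum(self):
        p = np.array([1.0, 1.0, 0.0, 0.0])
        q = np.array([0.0, 0.0, 2.0, 5.0])
        assert stationarity_gap(p, q) == 1.0

    def test_hand_value(self):
        assert stationarity_gap(np.array([3.0, 1.0]), np.array([1.0, 3.0])) == pytest.approx(0.5)

    def test_mismatched_supports_rejected(self):
        with pytest.raises(ValidationError):
            stationarity_gap(np.ones(3), np.ones(4))

    def test_zero_total_rejected(self):
        with pytest.raises(ComputationError):
            stationarity_gap(np.zeros(3), np.ones(3))

    @given(
        p=hnp.arrays(float, 30, elements=st.floats(0, 100)),
        q=hnp.arrays(float, 30, elements=st.floats(0, 100)),
    )
    def test_symmetry_and_range(self, p, q):
        if p.sum() == 0 or q.sum() == 0:
            return
        sg = stationarity_gap(p, q)
        assert 0.0 <= sg <= 1.0
        assert sg == pytest.approx(stationarity_gap(q, p), abs=1e-12)
        assert stationarity_gap(p, p) == 0.0

    def test_both_gap_readings_vanish_only_at_stationarity(self, growing_pop, stationary_pop):
        from demopair import remaining_years_gap

        # at stationarity both readings are zero ...
        pair_s = make_pair(stationary_pop)
        assert structural_gap(pair_s) == pytest.approx(0.0, abs=1e-12)
        assert remaining_years_gap(stationary_pop) == pytest.approx(0.0, abs=1e-12)
        # ... away from it both are positive but measure different departures
        pair = make_pair(growing_pop)
        assert structural_gap(pair) > 0.05
        assert remaining_years_gap(growing_pop) > 0.05
        assert structural_gap(pair) != pytest.approx(remaining_years_gap(growing_pop), abs=1e-3)


class TestTerminalDependency:
    def test_worked_five_year_product(self, gm_table):
        # one cohort of 100 at age 60 with q = 0.1 across the window
        q = np.full(101, 0.1)
        q[-1] = 1.0
        lt = complete_life_table(q=q)
        pop = _pop(lt, {60: 100.0})
        d5 = five_year_deaths(pop)
        assert d5[60] == pytest.approx(100 * (1 - 0.9**5))
        # denominator includes the age-60 cohort itself (20 <= 60 <= 64)
        assert terminal_dependency_ratio(pop) == pytest.approx(1 - 0.9**5)

    def test_immortal_below_top_is_zero(self):
        q = np.zeros(101)
        q[-1] = 1.0
        lt = complete_life_table(q=q)
        pop = _pop(lt, {30: 10.0, 50: 5.0})
        assert terminal_dependency_ratio(pop) == 0.0

    def test_absorbing_top_age(self, gm_table):
        # beyond omega q = 1: anyone within 5 years of omega dies in the window
        pop = _pop(gm_table, {99: 10.0, 40: 100.0})
        assert five_year_deaths(pop)[99] == pytest.approx(10.0)

    def test_per_individual_enumeration_oracle(self, rng, gm_table):
        n = rng.uniform(0, 10, size=101)
        pop = PopulationSnapshot(time=0, n=n, lifetable=gm_table)
        q_ext = np.concatenate([gm_table.q, np.ones(5)])
        total = 0.0
        for x in range(101):
            p_die = 0.0
            alive = 1.0
            for i in range(5):
                p_die += alive * q_ext[x + i]
                alive *= 1 - q_ext[x + i]
            total += n[x] * p_die
        assert five_year_deaths(pop).sum() == pytest.approx(total, rel=1e-12)


class TestOffsetDecomposition:
    def test_uniform_expectancy_shift_moves_so_by_the_shift(self, gm_table):
        then = build_stationary_population(gm_table, total=10.0, time=1970)
        improved = gm_table.with_expectancy_shift(2.0)
        now = PopulationSnapshot(time=2020, n=then.n.copy(), lifetable=improved)
        assert survival_offset(then, now) == pytest.approx(2.0)
        assert net_structural_aging(then, now) == pytest.approx(-2.0)

    def test_identical_snapshots_give_zero(self, gm_table):
        then = build_stationary_population(gm_table, total=10.0, time=1970)
        now = build_stationary_population(gm_table, total=10.0, time=2020)
        assert survival_offset(then, now) == 0.0
        assert net_structural_aging(then, now) == 0.0

    def test_same_timestamps_rejected(self, gm_table):
        a = build_stationary_population(gm_table, total=1.0, time=2020)
        with pytest.raises(ValidationError):
            survival_offset(a, a)

    def test_decomposition_identity_on_random_fixtures(self, rng, gm_table):
        for _ in range(20):
            n1 = rng.uniform(0, 100, size=101)
            n2 = rng.uniform(0, 100, size=101)
            then = PopulationSnapshot(time=1970, n=n1, lifetable=gm_table)
            now = PopulationSnapshot(time=2020, n=n2, lifetable=gm_table.with_expectancy_shift(rng.uniform(-3, 3)))
            delta_a = mean_age(now) - mean_age(then)
            so = survival_offset(then, now)
            nsa = net_structural_aging(then, now)
            assert so + nsa == pytest.approx(delta_a, abs=1e-9)


class TestComputeAll:
    def test_stationary_column_pattern(self, gm_table):
        pair = make_pair(build_stationary_population(gm_table, total=100.0, time=2020))
        obs, stat = compute_all(pair)
        assert stat.lpr == pytest.approx(1.0, abs=1e-3)
        assert stat.sg == pytest.approx(0.0, abs=1e-9)
        assert stat.stage == 3
        assert obs.so is None and obs.nsa is None

    def test_baseline_fills_so_nsa_with_decomposition(self, gm_table):
        pair_then = make_pair(
            make_stable_population(StableStructure(0.02, gm_table), total=100.0, time=1970)
        )
        pair_now = make_pair(
            make_stable_population(StableStructure(0.005, gm_table), total=120.0, time=2020)
        )
        obs, stat = compute_all(pair_now, pair_then)
        delta_a = mean_age(pair_now.observed) - mean_age(pair_then.observed)
        assert obs.so + obs.nsa == pytest.approx(delta_a, abs=1e-9)
        assert stat.nsa == pytest.approx(0.0, abs=1e-3)  # both members stationary

    def test_lotka_monotonicity_in_growth_rate(self, gm_table):
        rates = np.linspace(-0.03, 0.03, 7)
        ages = []
        lprs = []
        for r in rates:
            pop = make_stable_population(StableStructure(r, gm_table))
            ages.append(mean_age(pop))
            lprs.append(lifespan_parity_ratio(pop))
        assert np.all(np.diff(ages) < 0)  # mean age falls as growth rises
        assert np.all(np.diff(lprs) > 0)  # LPR rises with growth
        mid = lprs[3]  # r = 0
        assert mid == pytest.approx(1.0, abs=1e-3)
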