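"""One-shot transition rule, prevalence accounting and the enumeration oracle."""

import math

import numpy as np
import pytest

from depgame import (
    GameParams,
    Population,
    PopulationParams,
    Thresholds,
    assign_population,
    build_torus_neighbors,
    exact_prevalence_oracle,
    neighborhood_mean,
    neighborhood_means,
    prevalence,
    transition_states,
)


def make_population(n, payoffs, gender=None):
    """Hand-built population; strategy/kind codes are placeholders."""
    payoffs = np.asarray(payoffs, dtype=float).ravel()
    if gender is None:
        gender = np.zeros(n * n, dtype=np.int8)
    return Population(
        n=n,
        gender=np.asarray(gender, dtype=np.int8).ravel(),
        kind=np.zeros(n * n, dtype=np.int8),
        strategy=np.zeros(n * n, dtype=np.int8),
        payoff=payoffs,
    )


@pytest.fixture()
def grid3(gp):
    """3x3 fixture: center holds s = -1, the 8 others hold the listed payoffs."""
    payoffs = np.array([[15, 10, 9], [6, -1, 1], [-1, 9, 6]], dtype=float)
    gender = np.zeros((3, 3), dtype=np.int8)
    gender[1, 1] = 1  # center is a woman
    return make_population(3, payoffs, gender), build_torus_neighbors(3)


class TestNeighborhoodMean:
    def test_constructed_fixture(self, grid3):
        pop, nbr = grid3
        assert neighborhood_mean(pop, nbr, (1, 1)) == pytest.approx(55 / 8)

    def test_homogeneous_field(self):
        pop = make_population(5, np.full(25, 9.0))
        nbr = build_torus_neighbors(5)
        assert np.allclose(neighborhood_means(pop, nbr), 9.0)

    def test_own_cell_excluded(self):
        payoffs = np.zeros(16)
        payoffs[5] = 8.0  # only cell (1,1) is nonzero
        pop = make_population(4, payoffs)
        nbr = build_torus_neighbors(4)
        means = neighborhood_means(pop, nbr)
        assert means[5] == 0.0
        assert means[nbr.idx[5]].sum() == pytest.approx(8.0)


class TestTransition:
    def test_homogeneous_payoffs_never_depress(self):
        pop = make_population(5, np.full(25, 6.0))
        nbr = build_torus_neighbors(5)
        assert not transition_states(pop, nbr, Thresholds(0.01, 0.01)).any()

    def test_center_of_fixture_depressed(self, grid3):
        pop, nbr = grid3
        states = transition_states(pop, nbr, Thresholds(100.0, 0.6))
        assert states.reshape(3, 3)[1, 1]  # 55/8 - (-1) = 7.875 > 0.6
        assert states.sum() == 1  # men blocked by the huge sigma

    def test_strict_inequality_tie_stays_healthy(self):
        payoffs = np.zeros(9)
        payoffs[4] = -8.0  # q_bar(center) = 1, excess = 9 - ... build exact tie
        pop = make_population(3, payoffs)
        nbr = build_torus_neighbors(3)
        excess = neighborhood_means(pop, nbr)[4] - pop.payoff[4]
        states = transition_states(pop, nbr, Thresholds(excess, excess))
        assert not states[4]

    def test_boundary_threshold_gives_zero_prevalence(self, pp, gp, rng):
        """No excess can exceed t_A - s, the maximal payoff spread."""
        pop = assign_population(pp, gp, rng)
        nbr = build_torus_neighbors(pp.n)
        t_max = gp.t_A - gp.s
        assert not transition_states(pop, nbr, Thresholds(t_max, t_max)).any()

    @pytest.mark.parametrize("pair", [(0.5, 1.0), (1.0, 2.0), (-1.0, 0.0), (1.9, 4.75)])
    def test_depressed_sets_nested_in_threshold(self, small_pp, gp, rng, pair):
        """Lowering a threshold can only add depressed individuals."""
        low, high = pair
        pop = assign_population(small_pp, gp, rng)
        nbr = build_torus_neighbors(small_pp.n)
        at_low = transition_states(pop, nbr, Thresholds(low, low))
        at_high = transition_states(pop, nbr, Thresholds(high, high))
        assert not (at_high & ~at_low).any()


class TestPrevalence:
    def test_arithmetic_example(self):
        n = 100
        gender = np.concatenate([np.zeros(4930, np.int8), np.ones(5070, np.int8)])
        pop = make_population(n, np.zeros(n * n), gender)
        states = np.zeros(n * n, dtype=bool)
        states[:493] = True  # 493 of 4930 men
        states[4930 : 4930 + 1014] = True  # 1014 of 5070 women
        res = prevalence(states, pop)
        assert res.x_male == pytest.approx(0.1)
        assert res.x_female == pytest.approx(0.2)
        assert res.ratio == pytest.approx(2.0)
        assert res.x == pytest.approx(0.1507)

    def test_nobody_depressed_flags_undefined_ratio(self):
        gender = np.array([0, 1] * 8, np.int8)
        pop = make_population(4, np.zeros(16), gender)
        res = prevalence(np.zeros(16, bool), pop)
        assert res.x == 0.0
        assert not res.ratio_defined

    def test_only_women_depressed_gives_infinite_ratio(self):
        gender = np.array([0, 1] * 8, np.int8)
        pop = make_population(4, np.zeros(16), gender)
        res = prevalence(gender == 1, pop)
        assert res.ratio == math.inf

    def test_everyone_depressed(self):
        gender = np.array([0, 1] * 8, np.int8)
        pop = make_population(4, np.zeros(16), gender)
        res = prevalence(np.ones(16, bool), pop)
        assert res.x == 1.0 and res.ratio == 1.0

    def test_single_gender_rejected(self):
        pop = make_population(3, np.zeros(9))
        with pytest.raises(ValueError):
            prevalence(np.zeros(9, bool), pop)


class TestOracle:
    def test_degenerate_distribution_gives_zero(self, rng):
        gp1 = GameParams(t_A=15, t_B=10, r_A=9, r_B=6, p=1, s=-1, c=1.0)
        pp1 = PopulationParams(n=10, rho_NE=0.0, rho_NE_S=0.0, rho_E_S=1.0)  # all r_A
        res = exact_prevalence_oracle(pp1, gp1, Thresholds(0.5, 0.5))
        assert res.x == 0.0

    def test_threshold_below_minus_spread_gives_one(self, pp, gp):
        res = exact_prevalence_oracle(pp, gp, Thresholds(-16.5, -16.5))
        assert res.x == pytest.approx(1.0)

    def test_frozen_reference_values(self, pp, gp):
        """Regression constants computed once from the exact enumeration on
        the first-set payoff distribution."""
        res = exact_prevalence_oracle(pp, gp, Thresholds(0.8, 0.6))
        assert res.x_male == pytest.approx(0.3357623156476797, abs=1e-12)
        assert res.x_female == pytest.approx(0.3586357899956821, abs=1e-12)
        assert res.x == pytest.approx(0.3473591671421169, abs=1e-12)

    @pytest.mark.parametrize("n, n_seeds, th", [(30, 60, (2.0, 1.0)), (100, 60, (0.8, 0.6))])
    def test_simulation_agrees_with_oracle(self, gp, n, n_seeds, th):
        """Mean simulated prevalence matches the i.i.d. enumeration within
        Monte-Carlo error plus an O(1/n^2) exact-count correction."""
        pp = PopulationParams(n=n, male_fraction=0.493, rho_NE=0.188, rho_NE_S=0.05, rho_E_S=0.75)
        nbr = build_torus_neighbors(n)
        thr = Thresholds(*th)
        xs = []
        for seed in range(n_seeds):
            pop = assign_population(pp, gp, np.random.default_rng(3000 + seed))
            xs.append(prevalence(transition_states(pop, nbr, thr), pop).x)
        xs = np.array(xs)
        target = exact_prevalence_oracle(pp, gp, thr).x
        tol = 3 * xs.std(ddof=1) / np.sqrt(n_seeds) + 10.0 / n**2
        assert abs(xs.mean() - target) < tol

    def test_gender_symmetry_under_equal_thresholds(self, gp):
        """With sigma = tau the two genders are exchangeable: the paired
        male-female prevalence gap is centred on zero across seeds."""
        pp = PopulationParams(n=30, male_fraction=0.493, rho_NE=0.188, rho_NE_S=0.05, rho_E_S=0.75)
        nbr = build_torus_neighbors(30)
        thr = Thresholds(1.0, 1.0)
        gaps = []
        for seed in range(60):
            pop = assign_population(pp, gp, np.random.default_rng(7000 + seed))
            res = prevalence(transition_states(pop, nbr, thr), pop)
            gaps.append(res.x_male - res.x_female)
        gaps = np.array(gaps)
        assert abs(gaps.mean()) < 3 * gaps.std(ddof=1) / np.sqrt(len(gaps))
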