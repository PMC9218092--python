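"""Unit tests for the fitness and control equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hostcontrol.model_core import (
    BENEFIT_FORMS,
    HostPopulation,
    ModelParams,
    SymbiontPopulation,
    TraitGrid,
    benefit_as_printed,
    benefit_transform,
    control_effect,
    control_effect_matrix,
    host_feedback,
    host_fitness,
    mean_trait_after_control,
    mean_trait_after_control_vector,
    symbiont_feedback,
    symbiont_fitness_between,
    symbiont_fitness_within,
)

from conftest import oracle_bbar, oracle_q, random_symbiont_density


def point_mass(n, idx):
    d = np.zeros(n)
    d[idx] = 1.0
    return d


class TestParamsAndGrids:
    @pytest.mark.parametrize(
        "bad",
        [
            {"R": 1.5},
            {"M": -0.1},
            {"m": 2.0},
            {"f": -1.0},
            {"generation_ratio": 0},
            {"n_grid": 1},
            {"c_max": 0.0},
            {"benefit_form": "exponential"},
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)

    def test_grids_are_inclusive_and_increasing(self, params):
        for grid, hi in [(params.a_grid, 1.0), (params.c_grid, params.c_max)]:
            v = grid.values
            assert len(v) == params.n_grid
            assert v[0] == 0.0 and v[-1] == hi
            assert np.all(np.diff(v) > 0)

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError):
            TraitGrid(np.array([0.0, 0.5, 0.5, 1.0]))

    def test_densities_must_be_normalized(self):
        with pytest.raises(ValueError):
            SymbiontPopulation(np.full(11, 0.2))
        with pytest.raises(ValueError):
            HostPopulation(-np.ones((11, 11)) / 121)


class TestControlEffect:
    def test_zero_control_is_neutral(self, params, rng):
        S = SymbiontPopulation(random_symbiont_density(rng, params.n_grid))
        for b in params.b_grid.values:
            assert control_effect(b, 0.0, S, params) == pytest.approx(1.0, abs=1e-14)

    def test_clonal_population_escapes_discrimination(self, params):
        # R = 1: the denominator exponent vanishes, q = e^{b0 c}
        p = params.with_(R=1.0, f=0.0)
        S = SymbiontPopulation(point_mass(p.n_grid, 7))
        b0 = p.b_grid.values[7]
        for c in [0.5, 2.0, p.c_max]:
            assert control_effect(b0, c, S, p) == pytest.approx(math.exp(b0 * c))

    def test_three_point_uniform_example(self, params):
        # S uniform on {0, 0.5, 1}, R=0.5, f=0, c=1, b=1:
        # q = e / mean(e^0, e^0.25, e^0.5)
        p = params.with_(R=0.5, f=0.0)
        d = np.zeros(p.n_grid)
        d[[0, 5, 10]] = 1.0 / 3.0
        S = SymbiontPopulation(d)
        expected = math.e / np.mean([1.0, math.exp(0.25), math.exp(0.5)])
        assert control_effect(1.0, 1.0, S, p) == pytest.approx(expected, rel=1e-14)

    def test_control_out_of_range_rejected(self, params, rng):
        S = SymbiontPopulation(random_symbiont_density(rng, params.n_grid))
        with pytest.raises(ValueError):
            control_effect(0.5, params.c_max + 1.0, S, params)
        with pytest.raises(ValueError):
            control_effect(0.5, -0.5, S, params)

    def test_non_normalized_density_rejected(self, params):
        S = SymbiontPopulation(point_mass(params.n_grid, 0))
        S.density = S.density * 2.0  # corrupt after construction
        with pytest.raises(ValueError):
            control_effect(0.5, 1.0, S, params)

    def test_matrix_matches_scalar(self, params, rng):
        S = random_symbiont_density(rng, params.n_grid)
        Q = control_effect_matrix(S, params)
        pop = SymbiontPopulation(S)
        for i, b in enumerate(params.b_grid.values):
            for j, c in enumerate(params.c_grid.values):
                assert Q[i, j] == pytest.approx(
                    control_effect(b, c, pop, params), rel=1e-13
                )


class TestMeanTraitAfterControl:
    def test_no_control_returns_plain_mean(self, params, rng):
        d = random_symbiont_density(rng, params.n_grid)
        S = SymbiontPopulation(d)
        assert mean_trait_after_control(0.0, S, params) == pytest.approx(
            float(d @ params.b_grid.values)
        )

    def test_point_mass_is_invariant(self, params):
        S = SymbiontPopulation(point_mass(params.n_grid, 4))
        b0 = params.b_grid.values[4]
        for c in np.linspace(0, params.c_max, 7):
            assert mean_trait_after_control(c, S, params) == pytest.approx(b0)

    def test_suppression_cost_cancels(self, params, rng):
        d = random_symbiont_density(rng, params.n_grid)
        S = SymbiontPopulation(d)
        lo = mean_trait_after_control(3.0, S, params.with_(f=0.0))
        hi = mean_trait_after_control(3.0, S, params.with_(f=5.0))
        assert lo == pytest.approx(hi, rel=1e-13)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=11, max_size=11),
           st.floats(0.0, 9.9))
    def test_monotone_in_control(self, raw, c):
        # exponential tilting can only enrich high-cooperation mass
        p = ModelParams()
        d = np.array(raw)
        S = SymbiontPopulation(d / d.sum())
        assert (
            mean_trait_after_control(c + 0.1, S, p)
            >= mean_trait_after_control(c, S, p) - 1e-12
        )

    def test_matches_fine_grained_oracle(self, params, rng):
        d = random_symbiont_density(rng, params.n_grid)
        for c in np.linspace(0, params.c_max, 9):
            expected = oracle_bbar(c, d, params.b_grid.values, params.R, params.f)
            got = mean_trait_after_control(c, SymbiontPopulation(d), params)
            assert got == pytest.approx(expected, abs=1e-13)


class TestFeedbacks:
    def test_host_feedback_is_linear(self, params):
        assert host_feedback(0.0, params) == 0.0
        assert host_feedback(1.0, params) == params.y
        assert host_feedback(0.5, params) == pytest.approx(0.5 * params.y)

    def test_symbiont_feedback_limits(self, params, rng):
        d = random_symbiont_density(rng, params.n_grid)
        S = SymbiontPopulation(d)
        # R=1: feedback depends only on own cooperation
        p1 = params.with_(R=1.0)
        assert symbiont_feedback(0.7, 2.0, S, p1) == pytest.approx(0.7 * p1.x)
        # R=0: feedback depends only on the population mean after control
        p0 = params.with_(R=0.0)
        bbar = mean_trait_after_control(2.0, S, p0)
        assert symbiont_feedback(0.7, 2.0, S, p0) == pytest.approx(bbar * p0.x)

    def test_symbiont_feedback_hand_value(self, params):
        # R=0.5, x=2, b=1, bbar=0.5 (point mass at grid midpoint) -> 1.5
        S = SymbiontPopulation(point_mass(params.n_grid, 5))
        assert symbiont_feedback(1.0, 1.0, S, params) == pytest.approx(1.5)


class TestFitness:
    def test_baseline_host(self, params):
        S = SymbiontPopulation(point_mass(params.n_grid, 0))
        assert host_fitness(0.0, 0.0, S, params) == pytest.approx(1.0)

    def test_control_cost_only(self, params):
        # a=0, c=c_max: W_a = 1 - g
        S = SymbiontPopulation(point_mass(params.n_grid, 0))
        assert host_fitness(0.0, params.c_max, S, params) == pytest.approx(
            1.0 - params.g
        )

    def test_full_cooperation_payoff(self, params):
        # a=1, c=0, x=y=2, bbar=0.5 -> 0 + 2*2*0.5 = 2
        S = SymbiontPopulation(point_mass(params.n_grid, 5))
        assert host_fitness(1.0, 0.0, S, params) == pytest.approx(2.0)

    def test_symbiont_between_no_host_investment(self, params, rng):
        # H at (a=0, c=0): no feedback, W_b = 1 - b
        H = np.zeros((params.n_grid, params.n_grid))
        H[0, 0] = 1.0
        Hpop = HostPopulation(H)
        S = SymbiontPopulation(random_symbiont_density(rng, params.n_grid))
        for b in [0.0, 0.3, 1.0]:
            assert symbiont_fitness_between(b, Hpop, S, params) == pytest.approx(
                1.0 - b
            )

    def test_symbiont_between_point_host(self, params, rng):
        # b=0, H at (a, c=0): W_b = 1 + y*a*(1-R)*bbar(0)*x with q = 1
        d = random_symbiont_density(rng, params.n_grid)
        S = SymbiontPopulation(d)
        a_idx = 6
        a = params.a_grid.values[a_idx]
        H = np.zeros((params.n_grid, params.n_grid))
        H[a_idx, 0] = 1.0
        bbar0 = float(d @ params.b_grid.values)
        expected = 1.0 + params.y * a * (1.0 - params.R) * bbar0 * params.x
        got = symbiont_fitness_between(0.0, HostPopulation(H), S, params)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_within_favours_defectors_without_control(self, params, rng):
        H = np.zeros((params.n_grid, params.n_grid))
        H[3, 0] = 1.0  # all control mass at c = 0
        Hpop = HostPopulation(H)
        S = SymbiontPopulation(random_symbiont_density(rng, params.n_grid))
        W = [
            symbiont_fitness_within(b, Hpop, S, params)
            for b in params.b_grid.values
        ]
        assert W[0] == pytest.approx(2.0)  # (1-0) + q(0,0)=1
        assert np.all(np.diff(W) < 0)

    def test_heavy_suppression_kills_control_term(self, params, rng):
        p = params.with_(f=1e3)
        H = np.zeros((p.n_grid, p.n_grid))
        H[3, 5] = 1.0  # c > 0 so e^{-fc} bites
        S = SymbiontPopulation(random_symbiont_density(rng, p.n_grid))
        for b in [0.0, 0.5, 1.0]:
            got = symbiont_fitness_within(b, HostPopulation(H), S, p)
            assert got == pytest.approx(1.0 - b, abs=1e-12)

    def test_within_sign_flip_with_growing_control(self, params, rng):
        # q(1,c) - q(0,c) - 1 starts negative and turns positive as c grows
        p = params.with_(f=0.0)
        d = np.full(p.n_grid, 1.0 / p.n_grid)
        S = SymbiontPopulation(d)
        diffs = []
        for j in range(p.n_grid):
            H = np.zeros((p.n_grid, p.n_grid))
            H[0, j] = 1.0
            Hpop = HostPopulation(H)
            diffs.append(
                symbiont_fitness_within(1.0, Hpop, S, p)
                - symbiont_fitness_within(0.0, Hpop, S, p)
            )
        assert diffs[0] < 0 and diffs[-1] > 0


class TestBenefitTransforms:
    @pytest.mark.parametrize("form", BENEFIT_FORMS)
    def test_anchored_at_endpoints(self, form):
        assert benefit_transform(0.0, form) == pytest.approx(0.0)
        assert benefit_transform(1.0, form) == pytest.approx(1.0)

    def test_linear_is_identity(self):
        u = np.linspace(0, 1, 11)
        assert np.allclose(benefit_transform(u, "linear"), u)

    def test_diminishing_is_concave(self):
        u = np.linspace(0, 1, 101)
        y = benefit_transform(u, "diminishing")
        assert np.all(np.diff(y, 2) <= 1e-12)

    def test_accelerating_is_convex(self):
        u = np.linspace(0, 1, 101)
        y = benefit_transform(u, "accelerating")
        assert np.all(np.diff(y, 2) >= -1e-12)

    @pytest.mark.parametrize("form", BENEFIT_FORMS)
    def test_monotone_increasing(self, form):
        y = benefit_transform(np.linspace(0, 1, 101), form)
        assert np.all(np.diff(y) >= 0)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            benefit_transform(0.5, "quadratic")

    def test_printed_formulas_are_pathological(self):
        # exposed for inspection: the printed diminishing curve blows up
        # near b = 1/6 and the printed sigmoidal curve exceeds 1
        assert abs(benefit_as_printed(1 / 6 + 1e-9, "diminishing")) > 1e6
        assert benefit_as_printed(0.5, "sigmoidal") > 1.0
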