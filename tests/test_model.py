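"""Risk coefficients, the g-function, redundancy pruning and LP assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import geodeid as gd
from geodeid.model import lp_dimensions

from .conftest import make_problem

# Published demonstration scale: 264,327 children across 11,740 postal
# codes, 224 patients.
N_CITY = 264_327
S_CITY = 224


class TestRiskCoefficient:
    @pytest.mark.parametrize(
        "s_over_eps, expected",
        [(10, 3.783e-5), (20, 7.567e-5), (30, 11.350e-5), (33, 12.485e-5)],
    )
    def test_worst_case_coefficient_at_demonstration_scale(self, s_over_eps, expected):
        # nu = s/(N*eps) = (s/eps)/N at the published city scale, to 4-5
        # significant figures.
        nu = gd.risk_coefficient("wcmb", S_CITY, N_CITY, S_CITY / s_over_eps, 17)
        assert nu == pytest.approx(expected, rel=5e-4)

    def test_revised_equals_worst_case_for_large_areas(self):
        # min(s, n_i) attains s when n_i >= s.
        for n_i in (S_CITY, S_CITY + 1, 5000):
            assert gd.risk_coefficient("revised", S_CITY, N_CITY, 0.2, n_i) == (
                gd.risk_coefficient("wcmb", S_CITY, N_CITY, 0.2, n_i)
            )

    def test_revised_small_area_value(self):
        assert gd.risk_coefficient("revised", 100, 10_000, 0.5, 20) == pytest.approx(
            0.004
        )

    @settings(max_examples=100, derandomize=True)
    @given(
        s=st.integers(1, 5000),
        n_i=st.integers(1, 5000),
        eps=st.floats(0.01, 2.0),
    )
    def test_revised_never_exceeds_worst_case(self, s, n_i, eps):
        rev = gd.risk_coefficient("revised", s, N_CITY, eps, n_i)
        wc = gd.risk_coefficient("wcmb", s, N_CITY, eps, n_i)
        assert rev <= wc + 1e-15


class TestGFunction:
    def test_minimum_at_population_equal_to_patient_count(self):
        s, N, eps = 224, N_CITY, 0.2
        assert gd.g_function(s, s, N, eps) == pytest.approx((s / N) * (1 - 1 / eps))
        # Neighbouring integers sit above the minimum.
        for n_i in (s - 1, s + 1):
            assert gd.g_function(n_i, s, N, eps) >= gd.g_function(s, s, N, eps)

    def test_zero_crossing_at_s_over_epsilon(self):
        s, N, eps = 224, N_CITY, 0.2
        assert gd.g_function(s / eps, s, N, eps) == pytest.approx(0.0, abs=1e-15)

    def test_piecewise_value_above_s(self):
        # (n_i - s/eps)/N for n_i > s.
        assert gd.g_function(2000, 224, N_CITY, 0.2) == pytest.approx(880 / N_CITY)

    def test_continuity_at_s(self):
        s, N, eps = 224, N_CITY, 0.3
        below = gd.g_function(s, s, N, eps)
        above = gd.g_function(s * (1 + 1e-12), s, N, eps)
        assert below == pytest.approx(above, rel=1e-6)

    @settings(max_examples=200, derandomize=True)
    @given(
        n_i=st.integers(1, 3000),
        s=st.integers(1, 500),
        eps=st.floats(0.05, 0.999),
    )
    def test_sign_agrees_with_redundancy_rule(self, n_i, s, eps):
        # In the practical regime eps < 1 (where g is strictly negative
        # below s), g >= 0 and the pruning rule n_i >= s/eps coincide.
        g = gd.g_function(n_i, s, N_CITY, eps)
        redundant = gd.is_redundant_risk_constraint(n_i, s, eps)
        assert redundant == (g >= -1e-15)


class TestRedundancy:
    def test_boundary_population_is_redundant(self):
        # At n_i = s/eps the coefficient is exactly zero: still implied.
        assert gd.is_redundant_risk_constraint(1120, 224, 0.2)

    def test_epsilon_at_least_one_with_population_at_least_s(self):
        assert gd.is_redundant_risk_constraint(224, 224, 1.0)
        assert gd.is_redundant_risk_constraint(300, 224, 1.5)

    def test_small_area_not_redundant(self):
        assert not gd.is_redundant_risk_constraint(1000, 224, 0.2)


class TestLPDimensions:
    @pytest.mark.parametrize(
        "n_areas, k, n_vars, n_cons",
        [
            (11_740, None, 137_827_600, 137_839_340),  # full transitions
            (11_740, 10, 117_400, 129_140),
            (11_740, 30, 352_200, 363_940),  # 11,740 * (1 + 30)
            (2, None, 4, 6),
        ],
    )
    def test_published_problem_sizes(self, n_areas, k, n_vars, n_cons):
        assert lp_dimensions(n_areas, k) == (n_vars, n_cons)


class TestBuildLP:
    def test_counts_match_dimension_formula(self, grid_city):
        problem = make_problem(grid_city, s=30, epsilon=0.4, variant="revised", k=7)
        spec = gd.build_lp(problem, prune=False)
        assert spec.n_variables == 25 * 7
        assert spec.n_constraints_unpruned == 25 * (1 + 7)
        assert spec.n_constraints == spec.n_constraints_unpruned
        assert lp_dimensions(25, 7) == (spec.n_variables, spec.n_constraints_unpruned)

    def test_pruning_drops_exactly_large_area_rows(self, tiny_city):
        # s/eps = 100: only area 'd' (population 200) crosses the threshold.
        problem = make_problem(tiny_city, s=50, epsilon=0.5, variant="revised")
        spec = gd.build_lp(problem, prune=True)
        assert spec.pruned_origins == (3,)
        assert spec.n_constraints == spec.n_constraints_unpruned - 4

    def test_objective_coefficients_are_expectation_weighted_distances(self, tiny_city):
        problem = make_problem(tiny_city, s=10, epsilon=0.5, variant="revised")
        spec = gd.build_lp(problem, prune=False)
        N = tiny_city.N
        nb = problem.neighbors
        expected = []
        for i in range(len(tiny_city)):
            for d in nb.dist_m[i]:
                expected.append(tiny_city.population[i] / N * d)
        np.testing.assert_allclose(spec.c, expected)

    def test_row_sum_constraints_partition_variables(self, tiny_city):
        problem = make_problem(tiny_city, s=10, epsilon=0.5, variant="wcmb")
        spec = gd.build_lp(problem)
        A = spec.A_eq.toarray()
        assert A.sum() == spec.n_variables
        assert np.all(A.sum(axis=0) == 1)  # each variable in exactly one row

    def test_case1_unit_populations_reduce_to_probability_cap(self):
        # With every n_i = 1 the worst-case risk row for (i, j) rearranges to
        # P_ij <= (eps/s) * sum_k P_kj, the published unit-population
        # reduction (a cap of eps/s per unit of column mass).
        rng = np.random.default_rng(3)
        n = 6
        city = gd.LocationTable(
            area_ids=tuple(f"u{i}" for i in range(n)),
            lat=rng.uniform(45, 45.1, n),
            lon=rng.uniform(-75.1, -75, n),
            population=np.ones(n, dtype=int),
        )
        s, eps = 3, 0.5
        problem = make_problem(city, s=s, epsilon=eps, variant="wcmb")
        spec = gd.build_lp(problem, prune=False)
        A = spec.A_risk.toarray()
        N = float(n)
        for r, v in enumerate(spec.risk_var):
            j = spec.var_dest[v]
            # Independent rearrangement: (1/N) * colsum - (s/(N*eps)) * P_ij.
            expected = np.zeros(spec.n_variables)
            expected[spec.var_dest == j] = 1 / N
            expected[v] -= s / (N * eps)
            np.testing.assert_allclose(A[r], expected, atol=1e-15)

    def test_risk_rows_restricted_to_sparsified_columns(self, grid_city):
        problem = make_problem(grid_city, s=40, epsilon=0.3, variant="revised", k=4)
        spec = gd.build_lp(problem, prune=False)
        A = spec.A_risk.tocoo()
        for r, v in zip(A.row, A.col):
            bounded = spec.risk_var[r]
            assert spec.var_dest[v] == spec.var_dest[bounded]

    def test_epsilon_above_one_warns(self, tiny_city):
        nb = gd.nearest_neighbors(tiny_city, 2)
        with pytest.warns(UserWarning, match="impractical"):
            gd.DeidProblem(tiny_city, nb, 10, 6.79, "wcmb")
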