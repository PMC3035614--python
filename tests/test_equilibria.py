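"""ZNGIs, the reduced cubic, equilibrium enumeration and stability."""

import dataclasses

import numpy as np
import pytest

from ontoshift.equilibria import (
    ass_condition,
    classify_stability,
    coexistence_equilibria,
    reduced_cubic,
    stability_spectrum,
    zngi_adult,
    zngi_intersections,
    zngi_juvenile,
)
from ontoshift.fixtures import generate_fixtures
from ontoshift.models import (
    AdditionalResourcesParams,
    InterstageSharingParams,
    MultipleHabitatsParams,
    default_params,
    resource_equilibrium,
    rhs,
)


class TestZngi:
    @pytest.mark.parametrize("scenario", ["additional", "multiple", "sharing"])
    def test_isoclines_pass_through_origin(self, scenario):
        params = default_params(scenario)
        assert zngi_adult(params, 0.0) == 0.0
        assert zngi_juvenile(params, 0.0) == 0.0

    def test_adult_isocline_known_value(self, single_resource_params):
        # b*a*K*(1 - a*C_J/r)*C_J/d_A = 0.5*0.1*10*(1-0.5)*5/0.1
        assert zngi_adult(single_resource_params, 5.0) == pytest.approx(12.5)

    def test_adult_isocline_is_upward_convex_quadratic(self, additional_baseline):
        c = np.linspace(0.0, 8.0, 30)
        vals = zngi_adult(additional_baseline, c)
        second = np.diff(vals, 2)
        assert np.allclose(second, second[0]) and second[0] <= 0.0

    @pytest.mark.parametrize("scenario", ["additional", "sharing"])
    def test_isocline_intersection_is_full_equilibrium(self, scenario):
        """A point on both isoclines zeroes the complete right-hand side."""
        params = default_params(scenario)
        for c_J in zngi_intersections(params):
            c_A = zngi_adult(params, c_J)
            assert zngi_juvenile(params, c_A) == pytest.approx(c_J, rel=1e-7)
            R_J, R_A = resource_equilibrium(params, c_J, c_A)
            state = params.pack_state(R_J, R_A, c_J, c_A)
            np.testing.assert_allclose(
                rhs(params, state, validate=False), 0.0, atol=1e-8
            )

    def test_multiple_habitats_isocline_scales_with_habitat_ratio(self):
        base = default_params("multiple")
        doubled = dataclasses.replace(base, n_J=4.0)  # n_J/n_A doubles
        c = np.linspace(0.0, 8.0, 9)
        np.testing.assert_allclose(
            zngi_adult(doubled, c), 2.0 * zngi_adult(base, c), rtol=1e-12
        )

    def test_adult_isocline_monotone_in_second_juvenile_K(self, additional_baseline):
        """Raising K_J,2 raises ZNGI_A pointwise on the feasible range."""
        c = np.linspace(0.0, 9.99, 50)
        prev = zngi_adult(additional_baseline, c)
        for K2 in (15.0, 20.0, 30.0):
            p = dataclasses.replace(
                additional_baseline,
                K_J=np.array([additional_baseline.K_J[0], K2]),
            )
            cur = zngi_adult(p, c)
            assert np.all(cur >= prev - 1e-12)
            prev = cur

    def test_juvenile_isocline_monotone_in_second_adult_K(self, additional_baseline):
        c = np.linspace(0.0, 9.99, 50)
        prev = zngi_juvenile(additional_baseline, c)
        for K2 in (15.0, 20.0, 30.0):
            p = dataclasses.replace(
                additional_baseline,
                K_A=np.array([additional_baseline.K_A[0], K2]),
            )
            cur = zngi_juvenile(p, c)
            assert np.all(cur >= prev - 1e-12)
            prev = cur


class TestReducedCubic:
    def test_baseline_coefficients_match_hand_derivation(self, additional_baseline):
        """With p = sum(b a K), q = p a / r (equal rates), sigma = p - d_A,
        tau = q: L1 = -tau q^2, L2 = 2 tau p q, L3 = -(tau p^2 + q sigma d_A),
        L4 = p sigma d_A - d_J d_A^2."""
        poly = reduced_cubic(additional_baseline)
        assert poly.lam1 == pytest.approx(-1.0e-3)
        assert poly.lam2 == pytest.approx(2.0e-2)
        assert poly.lam3 == pytest.approx(-0.109)
        assert poly.lam4 == pytest.approx(0.089)

    @pytest.mark.parametrize("scenario", ["additional", "multiple", "sharing"])
    def test_roots_match_numeric_isocline_intersections(self, scenario):
        """Dual route: polynomial roots vs dense bisection on the isoclines."""
        for params in generate_fixtures(scenario, 100, seed=42):
            roots = [
                r for r, _ in reduced_cubic(params).real_roots() if r > 1e-8
            ]
            feasible = []
            for r in roots:
                try:
                    ca = zngi_adult(params, r)
                except ValueError:
                    continue
                if np.isfinite(ca) and ca > 1e-8:
                    feasible.append(r)
            numeric = zngi_intersections(params)
            assert len(numeric) == len(feasible)
            for a, b in zip(sorted(feasible), numeric):
                assert b == pytest.approx(a, rel=1e-6)

    def test_sharing_zero_cross_equals_single_resource_cubic(
        self, single_resource_params
    ):
        ps = InterstageSharingParams(K_J=10.0, K_A=10.0, a_JA=0.0, a_AJ=0.0)
        c_sharing = reduced_cubic(ps).coefficients
        c_add = reduced_cubic(single_resource_params).coefficients
        np.testing.assert_allclose(c_sharing, c_add, rtol=1e-12)

    def test_multiple_single_habitat_matches_additional_up_to_scale(
        self, single_resource_params
    ):
        pm = MultipleHabitatsParams(n_J=1, n_A=1)
        c1 = reduced_cubic(pm).coefficients
        c2 = reduced_cubic(single_resource_params).coefficients
        ratios = c1 / c2
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)

    def test_degenerate_lower_order_polynomial_roots(self):
        from ontoshift.equilibria import ReducedPolynomial

        quad = ReducedPolynomial(0.0, 1.0, -3.0, 2.0, scenario="additional")
        roots = [r for r, _ in quad.real_roots()]
        np.testing.assert_allclose(roots, [1.0, 2.0])
        assert quad.degree == 2

    def test_repeated_roots_merged_with_multiplicity(self):
        from ontoshift.equilibria import ReducedPolynomial

        # (x-1)^2 (x-3)
        poly = ReducedPolynomial(1.0, -5.0, 7.0, -3.0, scenario="additional")
        roots = poly.real_roots()
        assert [m for _, m in roots] == [2, 1]
        assert roots[0][0] == pytest.approx(1.0, abs=1e-6)


class TestCoexistenceEquilibria:
    def test_at_most_three_interior_equilibria(self):
        for scenario in ("additional", "multiple", "sharing"):
            for params in generate_fixtures(scenario, 400, seed=7):
                assert len(coexistence_equilibria(params, classify=False)) <= 3

    def test_baseline_has_three_verified_equilibria(self, additional_baseline):
        recs = coexistence_equilibria(additional_baseline)
        assert len(recs) == 3
        assert all(r.C_J > 0 and r.C_A > 0 for r in recs)
        assert all(np.min(r.R_J) > 0 and np.min(r.R_A) > 0 for r in recs)
        assert [r.C_J for r in recs] == sorted(r.C_J for r in recs)
        for r in recs:
            assert r.residual < 1e-8
            np.testing.assert_allclose(
                rhs(additional_baseline, r.state), 0.0, atol=1e-8
            )

    def test_nonviable_consumer_gives_no_equilibria(self):
        tiny = AdditionalResourcesParams(
            r_J=[1.0], K_J=[0.5], a_J=[0.1], b_J=[0.5],
            r_A=[1.0], K_A=[0.5], a_A=[0.1], b_A=[0.5],
        )
        assert coexistence_equilibria(tiny) == []
        assert not ass_condition(tiny).ass_exists

    def test_fractional_habitat_counts_supported(self):
        pm = MultipleHabitatsParams(n_J=2.0, n_A=2.5)
        recs = coexistence_equilibria(pm)
        assert len(recs) == 3
        assert all(r.residual < 1e-8 for r in recs)

    def test_heterogeneous_overrides_rejected(self):
        pm = MultipleHabitatsParams(n_J=2, n_A=2, K_J_override=[12.0, 8.0])
        with pytest.raises(ValueError, match="heterogeneous"):
            coexistence_equilibria(pm)


class TestStability:
    def test_middle_equilibrium_is_unstable(self, additional_baseline, bistable_params):
        for params in (additional_baseline, bistable_params):
            recs = coexistence_equilibria(params)
            assert len(recs) == 3
            assert recs[1].stability == "unstable"

    def test_bistable_point_outer_equilibria_stable(self, bistable_params):
        recs = coexistence_equilibria(bistable_params)
        labels = [r.stability for r in recs]
        assert labels[0].startswith("stable")
        assert labels[2].startswith("stable")

    def test_consumer_free_state_resource_block_stable(self, additional_baseline):
        params = additional_baseline
        state = params.pack_state(params.K_J, params.K_A, 0.0, 0.0)
        eig = stability_spectrum(params, state)
        # resource directions relax at rate -r at carrying capacity
        assert np.sum(np.isclose(eig.real, -1.0, atol=1e-6)) >= params.n_J + params.n_A

    def test_classify_accepts_state_vector(self, bistable_params):
        recs = coexistence_equilibria(bistable_params)
        assert classify_stability(bistable_params, recs[1].state) == "unstable"


class TestAssCondition:
    def test_ass_implies_three_records(self):
        for params in generate_fixtures("additional", 200, seed=3):
            diag = ass_condition(params)
            n = len(coexistence_equilibria(params, classify=False))
            if diag.ass_exists:
                assert n == 3
            assert diag.n_interior == n

    def test_baseline_inside_region(self, additional_baseline):
        diag = ass_condition(additional_baseline)
        assert diag.ass_exists and diag.discriminant > 0
        assert diag.n_interior == 3

    def test_strongly_imbalanced_second_resources_outside_region(
        self, additional_baseline
    ):
        p = dataclasses.replace(
            additional_baseline,
            K_J=np.array([10.0, 20.0]), K_A=np.array([10.0, 0.5]),
        )
        assert not ass_condition(p).ass_exists

    def test_sharing_resource_relabeling_invariance(self, sharing_baseline):
        for a_JA, a_AJ in [(0.002, 0.002), (0.05, 0.01), (0.2, 0.3)]:
            p = dataclasses.replace(sharing_baseline, a_JA=a_JA, a_AJ=a_AJ)
            d1 = ass_condition(p)
            d2 = ass_condition(p.swap_resource_roles())
            assert d1.ass_exists == d2.ass_exists
            assert d1.n_interior == d2.n_interior
            np.testing.assert_allclose(
                d1.interior_C_J, d2.interior_C_J, rtol=1e-8
            )

    def test_consumer_only_positivity_is_weaker(self, sharing_baseline):
        p = dataclasses.replace(sharing_baseline, a_JA=0.5, a_AJ=0.5)
        strict = ass_condition(p)
        loose = ass_condition(p, require_resource_positivity=False)
        assert not strict.ass_exists
        assert loose.n_interior >= strict.n_interior

    def test_own_stage_depletion_only_for_sharing(self, additional_baseline):
        with pytest.raises(ValueError, match="own-stage"):
            ass_condition(additional_baseline, depletion="own-stage")
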