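import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.polynomial import polynomial as npoly

import angiodyn as ad
from angiodyn.equilibria import GRID_POINTS, _scan_roots


def _perturbed(fixed, rng, scale=0.2):
    """Fixed preset with every rate nudged by up to +/-scale (valid by construction)."""
    data = {
        name: value * (1 + scale * (2 * rng.random() - 1))
        for name, value in fixed.to_dict().items()
    }
    return ad.ParameterSet.from_dict(data)


class TestConstraints:
    def test_fixed_preset_bounds(self, fixed):
        c = ad.constraints(fixed)
        assert (c.TC, c.TE, c.TA, c.Tg) == pytest.approx((9.0, 5.0, 5.0, 14.0))
        assert c.Tm == 5.0

    def test_bounds_scale_with_beta1(self, fixed):
        c = ad.constraints(fixed.replace(beta1=0.02))
        assert c.TC == pytest.approx(4.5)
        assert (c.TE, c.TA) == (5.0, 5.0)

    def test_gamma_zero_gives_infinite_te(self, fixed):
        c = ad.constraints(fixed.replace(gamma=0.0))
        assert math.isinf(c.TE)
        assert c.Tm == fixed.k3

    @given(
        beta1=st.floats(1e-4, 1.0),
        beta2=st.floats(1e-4, 1.0),
        mu3=st.floats(1e-4, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_tg_exceeds_tc_whenever_defined(self, fixed, beta1, beta2, mu3):
        # Tg = TC + alpha1*mu3/(beta1*beta2*k1): the vessel-positivity bound
        # is always the weaker one
        c = ad.constraints(fixed.replace(beta1=beta1, beta2=beta2, mu3=mu3))
        assert c.Tg > c.TC


class TestPolynomials:
    def test_vessel_decay_at_zero_tumour_load(self, fixed):
        pair = ad.build_polynomials(fixed)
        assert pair.g0 == pytest.approx(3.5)

    def test_f_roots(self, fixed):
        pair = ad.build_polynomials(fixed)
        assert npoly.polyval(0.0, pair.f) == 0.0
        # TA = k3 = 5 is a double root (and TE = 5 coincides at this preset)
        assert npoly.polyval(5.0, pair.f) == pytest.approx(0.0, abs=1e-10)
        assert npoly.polyval(5.0, npoly.polyder(pair.f)) == pytest.approx(0.0, abs=1e-10)

    def test_cubic_leading_coefficients(self, fixed):
        p = fixed
        pair = ad.build_polynomials(p)
        v1 = -p.eps * p.beta1 * p.beta2 * p.k1 / (p.mu5 * p.alpha3 * p.alpha1)
        v2 = (
            p.eps * (p.beta1 * p.beta2 * p.k1) ** 2 * p.k3
            / (p.mu5 * (p.alpha3 * p.alpha1) ** 2 * p.k4)
        )
        assert pair.v1 == pytest.approx(v1)
        assert pair.v2 == pytest.approx(v2)

    def test_general_variant_rejects_gamma_zero(self, fixed):
        with pytest.raises(ValueError, match="gamma0"):
            ad.build_polynomials(fixed.replace(gamma=0.0), "general")

    def test_unknown_variant_rejected(self, fixed):
        with pytest.raises(ValueError, match="variant"):
            ad.build_polynomials(fixed, "bogus")


class TestTrivialEquilibrium:
    def test_fixed_and_alternative_share_the_cancer_free_state(self, fixed, alternative):
        for p in (fixed, alternative):
            pt = ad.trivial_equilibrium(p)
            assert pt.feasible
            assert pt.coords == pytest.approx((9.0, 10.0, 0.0, 0.0, 0.0))

    def test_absent_when_growth_cannot_exceed_mortality(self, fixed):
        pt = ad.trivial_equilibrium(fixed.replace(alpha1=0.01))
        assert pt.label == "absent" and not pt.feasible


class TestCancerEquilibria:
    def test_fixed_preset_roots_and_coordinates(self, fixed_points):
        small, big = fixed_points
        assert small.feasible and big.feasible
        assert tuple(round(v, 2) for v in small.coords) == (8.92, 9.85, 0.08, 0.07, 0.71)
        assert tuple(round(v, 2) for v in big.coords) == (5.32, 2.64, 3.68, 0.88, 1.96)

    def test_no_cancer_state_beyond_the_beta2_threshold(self, fixed):
        assert ad.find_cancer_equilibria(fixed.replace(beta2=1.0)) == []

    def test_gamma_zero_matches_quadratic_formula(self, fixed):
        # independent oracle: closed-form roots of the reduced quadratic
        p = fixed.replace(gamma=0.0, eps=1.0)
        pair = ad.build_polynomials(p, "gamma0")
        oracle = np.sort(np.roots(pair.g1[::-1]))
        pts = ad.find_cancer_equilibria(p)
        assert len(pts) == 2
        assert [pt.T for pt in pts] == pytest.approx(list(oracle), rel=1e-9)
        for pt in pts:
            assert pt.coords.P == 0.0
            assert pt.coords.E == pytest.approx(10.0)

    def test_rhs_vanishes_at_every_feasible_point(self, fixed):
        rng = np.random.default_rng(7)
        params_list = [fixed] + [_perturbed(fixed, rng) for _ in range(10)]
        for p in params_list:
            for pt in ad.find_cancer_equilibria(p):
                assert np.max(np.abs(ad.rhs(pt.coords, p))) < 1e-8

    def test_scanner_agrees_with_dense_grid_oracle(self, fixed):
        # brute-force bracketing on a 100x finer grid finds the same roots
        rng = np.random.default_rng(11)
        params_list = [fixed] + [_perturbed(fixed, rng) for _ in range(20)]
        for p in params_list:
            pair = ad.build_polynomials(p)
            cons = ad.constraints(p)
            dense = _scan_roots(pair.residual, cons.Tm, 1_000_001)
            production = _scan_roots(pair.residual, cons.Tm, GRID_POINTS)
            assert len(dense) == len(production)
            assert production == pytest.approx(dense, rel=1e-6, abs=1e-12)

    def test_interior_root_count_is_zero_or_two(self, fixed):
        rng = np.random.default_rng(13)
        for p in [fixed] + [_perturbed(fixed, rng) for _ in range(20)]:
            n = len(ad.find_cancer_equilibria(p, include_infeasible=True))
            assert n in (0, 2)

    def test_positive_axis_root_count_is_even(self, fixed):
        # over (0, inf) the quartic residual has 0, 2 or 4 positive roots
        rng = np.random.default_rng(17)
        for p in [fixed] + [_perturbed(fixed, rng) for _ in range(20)]:
            pair = ad.build_polynomials(p)
            d = npoly.polysub(pair.f, pair.g)
            roots = np.roots(d[::-1])
            n_pos = int(np.sum((np.abs(roots.imag) < 1e-9) & (roots.real > 1e-12)))
            assert n_pos in (0, 2, 4)

    def test_branches_approach_each_other_with_beta2(self, fixed):
        # toward the fold the small root rises and the big root falls
        prev_small, prev_big = None, None
        for b2 in (0.01, 0.02, 0.03, 0.04, 0.045):
            pts = ad.find_cancer_equilibria(fixed.replace(beta2=b2))
            small = next(pt.T for pt in pts if pt.label == "small")
            big = next(pt.T for pt in pts if pt.label == "big")
            if prev_small is not None:
                assert small > prev_small
                assert big < prev_big
            prev_small, prev_big = small, big


class TestDisplacementEquilibrium:
    def test_tumour_level_is_pinned_above_beta1c(self, fixed):
        pt = ad.displacement_equilibrium(fixed.replace(beta1=10.0))
        assert pt.feasible
        assert pt.coords.C == 0.0
        assert pt.T == pytest.approx(4.2306, abs=5e-5)

    def test_coordinates_do_not_depend_on_beta1(self, fixed):
        a = ad.displacement_equilibrium(fixed.replace(beta1=10.0))
        b = ad.displacement_equilibrium(fixed.replace(beta1=100.0))
        assert tuple(a.coords) == pytest.approx(tuple(b.coords), rel=1e-12)

    def test_vessel_coordinate_consistent_with_general_formula(self, fixed):
        # substituting C = 0 into the general A-balance gives
        # A = k3*mu3/(alpha3*(k3 - T))
        p = fixed.replace(beta1=10.0)
        pt = ad.displacement_equilibrium(p)
        assert pt.coords.A == pytest.approx(
            p.k3 * p.mu3 / (p.alpha3 * (p.k3 - pt.T)), rel=1e-12
        )
        # and the full rhs vanishes there
        assert np.max(np.abs(ad.rhs(pt.coords, p))) < 1e-8

    def test_infeasible_below_beta1c(self, fixed):
        pt = ad.displacement_equilibrium(fixed)  # beta1 = 0.01 < beta1_c
        assert not pt.feasible
        assert "below beta1c" in pt.note


class TestVariantLimits:
    def test_eps0_variant_is_the_limit_of_the_general_balance(self, fixed):
        # roots of the eps = 0 reduced balance match the general quartic
        # evaluated at vanishingly small eps
        limit = ad.find_cancer_equilibria(fixed.replace(eps=1e-10))
        reduced = ad.find_cancer_equilibria(fixed.replace(eps=0.0), variant="eps0")
        assert [pt.T for pt in reduced] == pytest.approx(
            [pt.T for pt in limit], rel=1e-6
        )

    def test_delta_inf_variant_drops_the_survival_factor(self, fixed):
        pair = ad.build_polynomials(fixed)
        pair_inf = ad.build_polynomials(fixed, "delta_inf")
        scale = (fixed.mu4 + fixed.delta) / fixed.delta
        assert pair_inf.f == pytest.approx(pair.f * scale)
        assert pair_inf.g1 == pytest.approx(pair.g1)
        assert pair_inf.g2 == pytest.approx(pair.g2)
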