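import numpy as np
import pytest

import angiodyn as ad


def _candidates(params):
    return [ad.trivial_equilibrium(params)] + ad.find_cancer_equilibria(params)


class TestIntegrate:
    def test_step_halving_leaves_final_state_unchanged(self, fixed):
        # 4th-order scheme: halving dt moves the converged final state by
        # far less than 1e-6
        init = ad.pulse_initial_state(fixed, 1.024, full_c0=True)
        a = ad.integrate(fixed, init, 2000.0, 0.01).final_state
        b = ad.integrate(fixed, init, 2000.0, 0.005).final_state
        assert np.max(np.abs(np.subtract(a, b))) < 1e-6

    def test_decoupled_compartments_follow_the_logistic_solution(self, fixed):
        # with no coupling and no tumour compartments, C and E are pure
        # logistic growth with rate r = alpha - mu and capacity K*r/alpha
        p = fixed.replace(gamma=0.0, eps=0.0, beta1=0.0, beta2=0.0)
        init = ad.State(2.0, 3.0, 0.0, 0.0, 0.0)
        traj = ad.integrate(p, init, 500.0, 0.01)

        def logistic(y0, alpha, mu, k, t):
            r = alpha - mu
            k_eff = k * r / alpha
            return k_eff / (1 + (k_eff / y0 - 1) * np.exp(-r * t))

        c_exact = logistic(2.0, p.alpha1, p.mu1, p.k1, traj.times)
        e_exact = logistic(3.0, p.alpha2, p.mu2, p.k2, traj.times)
        assert np.max(np.abs(traj.component("C") - c_exact) / c_exact) < 1e-6
        assert np.max(np.abs(traj.component("E") - e_exact) / e_exact) < 1e-6
        # and they converge to the cancer-free coordinates
        assert traj.final_state.C == pytest.approx(9.0, rel=1e-6)
        assert traj.final_state.E == pytest.approx(10.0, rel=1e-6)

    def test_cancer_equilibrium_persists(self, fixed):
        # printed coordinates are rounded to 2 decimals; the trajectory must
        # stay within that rounding of its start
        init = ad.State(5.32, 2.64, 3.68, 0.88, 1.96)
        traj = ad.integrate(fixed, init, 1000.0, 0.01)
        assert np.max(np.abs(traj.states - np.asarray(init))) < 1e-2

    def test_states_stay_non_negative(self, fixed):
        runs = [
            (fixed, ad.pulse_initial_state(fixed, 1.024, full_c0=True)),
            (fixed.replace(beta2=1.0), ad.pulse_initial_state(fixed.replace(beta2=1.0), 100.0)),
            (fixed.replace(beta1=10.0), ad.pulse_initial_state(fixed.replace(beta1=10.0), 0.152, full_c0=True)),
        ]
        for p, init in runs:
            traj = ad.integrate(p, init, 3000.0, 0.01)
            assert np.min(traj.states) >= 0.0

    def test_final_partial_step_lands_exactly_on_t_end(self, fixed):
        traj = ad.integrate(fixed, ad.State(9, 10, 0, 0, 0), 10.005, 0.01)
        assert traj.times[-1] == pytest.approx(10.005, abs=1e-9)

    def test_argument_validation(self, fixed):
        init = ad.State(9, 10, 0, 0, 0)
        with pytest.raises(ValueError, match="t_end"):
            ad.integrate(fixed, init, -1.0, 0.01)
        with pytest.raises(ValueError, match="dt"):
            ad.integrate(fixed, init, 10.0, 20.0)


class TestClassifyAttractor:
    def test_pulse_on_either_side_of_the_separatrix(self, fixed):
        cands = _candidates(fixed)
        lo = ad.integrate(fixed, ad.pulse_initial_state(fixed, 1.023, full_c0=True), 5000.0, 0.01)
        hi = ad.integrate(fixed, ad.pulse_initial_state(fixed, 1.024, full_c0=True), 5000.0, 0.01)
        assert ad.classify_attractor(lo, cands).label == "trivial"
        assert ad.classify_attractor(hi, cands).label == "big"

    def test_stationary_trajectory_is_trivial(self, fixed):
        traj = ad.integrate(fixed, ad.pulse_initial_state(fixed, 0.0), 100.0, 0.01)
        v = ad.classify_attractor(traj, _candidates(fixed))
        assert v.label == "trivial"
        assert v.distance_at_end < 1e-9

    def test_sustained_oscillations_inside_the_hopf_window(self, fixed):
        p = fixed.replace(gamma=0.0245)
        traj = ad.integrate(p, ad.pulse_initial_state(p, 0.45, full_c0=True), 20000.0, 0.01)
        v = ad.classify_attractor(traj, _candidates(p))
        assert v.label == "limit_cycle"
        assert v.oscillation_amplitude > 1e-3

    def test_decay_after_oscillations_beyond_the_window(self, fixed):
        # just past the cycle exit the trajectory oscillates, then regresses
        p = fixed.replace(gamma=0.02520)
        traj = ad.integrate(p, ad.pulse_initial_state(p, 0.42, full_c0=True), 20000.0, 0.01)
        assert ad.classify_attractor(traj, _candidates(p)).label == "trivial"

    def test_break_point_manifold_separates_the_basins(self, fixed, fixed_points):
        # perturbing only T off the break-point coordinates selects the basin
        small, _ = fixed_points
        cands = _candidates(fixed)
        c = small.coords
        for sign, expected in [(-1, "trivial"), (+1, "big")]:
            init = ad.State(c.C, c.E, c.T * (1 + sign * 1e-3), c.P, c.A)
            traj = ad.integrate(fixed, init, 5000.0, 0.01)
            assert ad.classify_attractor(traj, cands).label == expected

    def test_empty_candidate_list_rejected(self, fixed):
        traj = ad.integrate(fixed, ad.State(9, 10, 0, 0, 0), 10.0, 0.01)
        with pytest.raises(ValueError, match="candidate"):
            ad.classify_attractor(traj, [])


class TestOnsetTime:
    def test_baseline_relapse_around_400_days(self, fixed, fixed_points):
        _, big = fixed_points
        init = ad.pulse_initial_state(fixed, 1.024, full_c0=True)
        traj = ad.integrate(fixed, init, 3000.0, 0.01)
        onset = ad.onset_time(traj, big)
        assert 300 < onset < 500

    def test_subcritical_pulse_never_reaches_onset(self, fixed, fixed_points):
        _, big = fixed_points
        init = ad.pulse_initial_state(fixed, 0.5, full_c0=True)
        traj = ad.integrate(fixed, init, 3000.0, 0.01)
        assert ad.onset_time(traj, big) is None

    def test_oversized_pulse_is_timed_at_the_relapse(self, alternative):
        # a pulse that starts above threshold, dips and relapses must be
        # timed at the upward crossing, not at t = 0
        p = alternative.replace(delta=0.001)
        big = next(pt for pt in ad.find_cancer_equilibria(p) if pt.label == "big")
        init = ad.pulse_initial_state(p, 0.25)
        traj = ad.integrate(p, init, 3000.0, 0.01)
        onset = ad.onset_time(traj, big)
        assert onset is not None and onset > 100.0
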