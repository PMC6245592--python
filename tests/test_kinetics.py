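"""Photosynthetic-factory kinetics: reparametrization, generator spectrum,
steady states, full/reduced dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm, null_space

import psfcav as p
from psfcav.kinetics import (DARK_STATE, PSFRates, PSFReparam, PSFState,
                             constant_light, reduced_fixed_point, reduced_rate,
                             simulate_reduced, yA_ss, yB_ss)


def invariant_distribution(M):
    """Normalized nullspace vector of a generator (independent oracle)."""
    v = null_space(M)[:, 0]
    return v / v.sum()


# ---------------------------------------------------------------- reparam

class TestReparametrize:
    def test_wu_merchuk_printed_values(self, wu_rates):
        q = p.reparametrize(wu_rates)
        # optimal irradiance ~250 uE m^-2 s^-1; q2 rounds to the 0.3 in use
        assert q.q1 == pytest.approx(250.0, abs=0.5)
        assert q.q2 == pytest.approx(0.3016, abs=5e-4)
        assert round(q.q2, 1) == 0.3
        assert q.q4 == pytest.approx(wu_rates.alpha * q.q1, rel=1e-14)
        assert q.q5 == pytest.approx(wu_rates.beta / wu_rates.alpha, rel=1e-14)

    def test_unit_rates_hand_evaluation(self):
        q = p.reparametrize(PSFRates(1.0, 1.0, 1.0, 1.0, kappa=1.0))
        assert (q.q1, q.q2, q.q3, q.q4, q.q5) == pytest.approx((1, 0.5, 1, 1, 1))

    @pytest.mark.parametrize("field", ["alpha", "beta", "gamma", "delta"])
    def test_nonpositive_rate_rejected_naming_field(self, field):
        kw = dict(alpha=1e-3, beta=1e-6, gamma=0.1, delta=1e-4)
        kw[field] = -1.0
        with pytest.raises(ValueError, match=field):
            PSFRates(**kw)


# -------------------------------------------------------------- generator

class TestReactionGenerator:
    @pytest.mark.parametrize("u", [0.0, 0.3, 1.0, 10.0, 250.0])
    def test_column_sums_vanish(self, u, reparam, wu_rates):
        assert np.allclose(p.reaction_generator(u, reparam).sum(axis=0), 0.0,
                           atol=1e-15)
        assert np.allclose(p.reaction_generator_rates(u, wu_rates).sum(axis=0),
                           0.0, atol=1e-15)

    def test_printed_eigenvalues_at_optimal_irradiance(self, wu_rates):
        """At I = 250 uE m^-2 s^-1 the nonzero eigenvalues are -0.63 and
        -0.59e-3 s^-1 (two significant figures)."""
        M = p.reaction_generator_rates(250.0, wu_rates)
        lam = sorted(np.linalg.eigvals(M).real, key=abs, reverse=True)
        assert lam[0] == pytest.approx(-0.63, abs=0.005)
        assert lam[1] == pytest.approx(-0.59e-3, abs=0.005e-3)
        assert abs(lam[2]) < 1e-14

    def test_dark_spectrum_is_triangular(self, wu_rates):
        """u = 0 leaves the light-independent matrix with eigenvalues
        {0, -gamma, -delta} (it is triangular in the original rates)."""
        M = p.reaction_generator_rates(0.0, wu_rates)
        lam = np.sort(np.linalg.eigvals(M).real)
        expected = np.sort([0.0, -wu_rates.gamma, -wu_rates.delta])
        assert lam == pytest.approx(expected, abs=1e-14)

    def test_parametrizations_agree(self, wu_rates):
        q = p.reparametrize(wu_rates)
        for u in (0.1, 1.0, 7.5):
            assert np.allclose(p.reaction_generator(u, q),
                               p.reaction_generator_rates(u * q.q1, wu_rates),
                               rtol=1e-12, atol=1e-15)

    def test_negative_irradiance_rejected(self, reparam, wu_rates):
        with pytest.raises(ValueError):
            p.reaction_generator(-0.1, reparam)
        with pytest.raises(ValueError):
            p.reaction_generator_rates(-1.0, wu_rates)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(u=st.floats(min_value=0.0, max_value=100.0))
    def test_spectrum_structure_for_all_irradiances(self, u):
        """One zero eigenvalue (conservation) and two with negative real
        part, for every admissible irradiance."""
        lam = np.linalg.eigvals(p.reaction_generator(u, p.CASE_STUDY_REPARAM))
        lam = lam[np.argsort(np.abs(lam))]
        assert abs(lam[0]) < 1e-12
        assert (lam[1:].real < 0).all()


# ----------------------------------------------------------- steady state

class TestSteadyState:
    @pytest.mark.parametrize("u, expected", [
        (1.0, (0.1875, 0.625, 0.1875)),
        (0.0, (1.0, 0.0, 0.0)),
        # direct evaluation of the closed form at u = 10, q2 = 0.3
        (10.0, (1.0 / 134.333333333333, (10 / 0.3) / 134.333333333333,
                100.0 / 134.333333333333)),
    ])
    def test_closed_form_values(self, u, expected):
        ss = p.steady_state(u, q2=0.3)
        assert (ss.yR, ss.yA, ss.yB) == pytest.approx(expected, abs=1e-12)

    def test_maximum_at_optimal_irradiance(self):
        """yA_ss peaks at u = 1, i.e. at I = q1."""
        u = np.linspace(0.01, 10.0, 5000)
        vals = yA_ss(u, 0.3)
        assert u[np.argmax(vals)] == pytest.approx(1.0, abs=0.01)
        assert vals.max() == pytest.approx(0.625, abs=1e-5)

    @pytest.mark.parametrize("u", [0.01, 0.1, 1.0, 10.0, 100.0])
    def test_agrees_with_nullspace_to_inhibition_order(self, u, reparam):
        """The closed form is the q5 -> 0 reduction of the generator's
        invariant distribution; agreement is O(q5) ~ 3e-4 for the real
        parameter set."""
        v = invariant_distribution(p.reaction_generator(u, reparam))
        assert v == pytest.approx(p.steady_state(u, reparam).as_array(),
                                  abs=2.0 * reparam.q5)

    @pytest.mark.parametrize("u", [0.1, 1.0, 10.0])
    def test_nullspace_gap_vanishes_linearly_with_q5(self, u, reparam):
        """The closed-form/nullspace gap is first order in the inhibition
        ratio q5: shrinking q5 a hundredfold shrinks the gap a hundredfold."""
        gaps = []
        for q5 in (1e-4, 1e-6):
            rp = PSFReparam(q1=reparam.q1, q2=reparam.q2, q3=reparam.q3,
                            q4=reparam.q4, q5=q5)
            v = invariant_distribution(p.reaction_generator(u, rp))
            gaps.append(np.abs(v - p.steady_state(u, q2=reparam.q2).as_array()).max())
        assert gaps[1] < 1e-5
        assert gaps[0] / gaps[1] == pytest.approx(100.0, rel=0.1)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            p.steady_state(-1.0, q2=0.3)
        with pytest.raises(ValueError):
            p.steady_state(1.0, q2=0.0)


# ---------------------------------------------------------- full dynamics

class TestSimulateFull:
    def test_conserves_total_fraction(self, reparam):
        traj = p.simulate_full(constant_light(1.0), DARK_STATE, (0.0, 20000.0),
                               dt_out=200.0, reparam=reparam)
        assert np.abs(traj.y.sum(axis=1) - 1.0).max() < 1e-8

    def test_invariant_state_is_fixed_point(self, reparam):
        y_inv = invariant_distribution(p.reaction_generator(1.0, reparam))
        traj = p.simulate_full(constant_light(1.0), PSFState.from_array(y_inv),
                               (0.0, 5000.0), dt_out=500.0, reparam=reparam)
        assert np.abs(traj.y - y_inv).max() < 1e-7

    def test_long_time_convergence_to_steady_state(self, reparam):
        traj = p.simulate_full(constant_light(1.0), DARK_STATE, (0.0, 30000.0),
                               reparam=reparam)
        y_inv = invariant_distribution(p.reaction_generator(1.0, reparam))
        assert np.abs(traj.y[-1] - y_inv).max() < 1e-6
        # and the printed steady values hold at their printed precision
        assert traj.y[-1] == pytest.approx(
            p.steady_state(1.0, reparam).as_array(), abs=5e-4)

    def test_two_phase_dynamics(self, reparam):
        """From the dark state under u = 1: a fast rise of yA within seconds,
        then a slow decline as the inhibited pool yB builds up over hours."""
        traj = p.simulate_full(constant_light(1.0), DARK_STATE, (0.0, 20000.0),
                               dt_out=1.0, reparam=reparam)
        peak_idx = np.argmax(traj.yA)
        assert traj.t[peak_idx] < 60.0
        assert traj.yA[peak_idx] > 0.7
        assert traj.yA[-1] < traj.yA[peak_idx] - 0.1
        assert traj.yB[-1] > 0.15

    def test_matrix_exponential_oracle(self, reparam):
        """Constant-light integration agrees with the exact propagator."""
        M = p.reaction_generator(0.7, reparam)
        traj = p.simulate_full(constant_light(0.7), DARK_STATE, (0.0, 100.0),
                               reparam=reparam)
        assert traj.y[-1] == pytest.approx(expm(M * 100.0) @ DARK_STATE.as_array(),
                                           abs=1e-8)

    def test_invalid_span_rejected(self, reparam):
        with pytest.raises(ValueError):
            p.simulate_full(constant_light(1.0), DARK_STATE, (0.0, -5.0),
                            reparam=reparam)


# ------------------------------------------------------- reduced dynamics

class TestSimulateReduced:
    def test_fixed_point_is_max_steady_fraction(self, reparam):
        assert reduced_fixed_point(1.0, 1.0, reparam) == pytest.approx(0.625)
        traj = simulate_reduced(1.0, 1.0, 0.625, (0.0, 50.0), reparam)
        assert np.abs(traj.yA - 0.625).max() < 1e-14

    def test_relaxation_time_constant(self, reparam):
        """t_r = 1/[q4 (u_av + q2)] = 1.538 s for q4 = 0.5, q2 = 0.3."""
        assert 1.0 / reduced_rate(1.0, reparam) == pytest.approx(1.538, abs=2e-3)
        traj = simulate_reduced(1.0, 1.0, 0.0, np.linspace(0, 10, 500), reparam)
        resid = 0.625 - traj.yA
        slope = np.polyfit(traj.t, np.log(resid), 1)[0]
        assert -1.0 / slope == pytest.approx(1.538, abs=2e-3)

    def test_converges_to_local_fixed_point(self, reparam):
        u_loc = 0.4
        fp = reduced_fixed_point(u_loc, 1.0, reparam)
        traj = simulate_reduced(u_loc, 1.0, 0.0, (0.0, 60.0), reparam)
        assert traj.yA[-1] == pytest.approx(fp, abs=1e-9)
        # frozen inhibited pool
        assert np.allclose(traj.yB, yB_ss(1.0, reparam.q2))

    def test_zero_average_irradiance_rejected(self, reparam):
        with pytest.raises(ValueError):
            simulate_reduced(1.0, 0.0, 0.0, (0.0, 1.0), reparam)

    def test_matches_full_model_on_fast_time_scale(self, reparam):
        """Starting the full model with yB at its slow quasi-steady value,
        the reduced and full yA agree within 0.02 for t <= 40 s."""
        u = 1.0
        yB0 = float(yB_ss(u, reparam.q2))
        y0 = PSFState(1.0 - yB0, 0.0, yB0)
        full = p.simulate_full(constant_light(u), y0, (0.0, 40.0), dt_out=0.5,
                               reparam=reparam)
        red = simulate_reduced(u, u, 0.0, full.t, reparam)
        assert np.abs(full.yA - red.yA).max() < 0.02


# -------------------------------------------------------------- stiffness

class TestStiffnessRatio:
    def test_order_thousand_at_optimal_irradiance(self, wu_rates):
        ratio = p.stiffness_ratio(1.0, p.reparametrize(wu_rates))
        assert ratio == pytest.approx(1.07e3, rel=0.02)

    def test_balanced_rates_are_not_stiff(self):
        q = p.reparametrize(PSFRates(1.0, 1.0, 1.0, 1.0, kappa=1.0))
        assert p.stiffness_ratio(1.0, q) < 10.0
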