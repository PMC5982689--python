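"""Duffing dynamics: Ritz steady state, time-domain oracle, resonance and
quality factor."""

import math

import numpy as np
import pytest

import gripsim as gs
from gripsim.config import DriveSignal
from gripsim.dynamics import DuffingParams, ritz_response, time_integrate

# weakly nonlinear parameters in the device's range
P_WEAK = DuffingParams(J_b=5.86e-15, c_amT=7e-13, k_lin=1.05e-7,
                       alpha_b=0.0148, B=2.1e-13)
P_LIN = DuffingParams(J_b=5.86e-15, c_amT=7e-13, k_lin=4.9557e-8,
                      alpha_b=0.0, B=2.1e-13)


class TestResonantFrequency:
    def test_published_inputs_give_463_hz(self):
        f = gs.resonant_frequency(4.9557e-8, 5.86e-15)
        assert f == pytest.approx(463.8, rel=5e-3)

    def test_quadrupled_stiffness_doubles_frequency(self):
        assert gs.resonant_frequency(4e-8, 1e-15) == pytest.approx(
            2 * gs.resonant_frequency(1e-8, 1e-15), rel=1e-14)

    def test_cell_stiffness_adds_before_sqrt(self, bhp_scenario):
        p = gs.assemble_motion_equation(bhp_scenario)
        f = gs.resonant_frequency(p.k_lin, p.J_b)
        assert f == pytest.approx(
            math.sqrt(p.k_lin / p.J_b) / (2 * math.pi), rel=1e-14)
        assert f > gs.resonant_frequency(4.9557e-8, p.J_b)


class TestAssembly:
    def test_no_cell_no_nonlinearity(self, paper_scenario):
        scn = paper_scenario.with_drive(DriveSignal(V0=0.0, V1=0.25,
                                                    omega=2 * math.pi * 463))
        p = gs.assemble_motion_equation(scn)
        assert p.alpha_b == 0.0 and p.B == 0.0
        assert p.k_lin == pytest.approx(4.9557e-8)

    def test_cell_raises_linear_stiffness(self, paper_scenario, bhp_scenario):
        p0 = gs.assemble_motion_equation(paper_scenario)
        p1 = gs.assemble_motion_equation(bhp_scenario)
        assert p1.k_lin > p0.k_lin
        assert p1.alpha_b > 0

    def test_unit_system_invariance(self, tmp_path, bhp_scenario):
        """Re-expressing the config in different (equivalent) units leaves the
        assembled parameters untouched."""
        from gripsim.config import scenario_to_dict, scenario_from_dict
        raw = scenario_to_dict(bhp_scenario)
        raw["inertia"]["J_b"] = "5.86e-15 kg*m^2"
        raw["cell"]["E_c"] = "2.797e-6 GPa"
        raw["kinematics"]["r_c"] = "2.5 mm"
        scn2 = scenario_from_dict(raw)
        p1 = gs.assemble_motion_equation(bhp_scenario)
        p2 = gs.assemble_motion_equation(scn2)
        assert p2.k_lin == pytest.approx(p1.k_lin, rel=1e-12)
        assert p2.alpha_b == pytest.approx(p1.alpha_b, rel=1e-12)


class TestRitzResponse:
    def test_linear_limit_equals_closed_form(self):
        omega = 2 * math.pi * np.linspace(200, 900, 401)
        resp = ritz_response(P_LIN, omega)
        c1 = np.array([b[0][0] for b in resp.branches])
        expected = P_LIN.B / np.sqrt(
            (P_LIN.k_lin - P_LIN.J_b * omega**2) ** 2 + (P_LIN.c_amT * omega) ** 2)
        np.testing.assert_allclose(c1, expected, rtol=1e-12)

    def test_phase_passes_quadrature_at_resonance(self):
        omega = np.array([0.5, 1.0, 2.0]) * P_LIN.omega_n
        resp = ritz_response(P_LIN, omega)
        psi = [b[0][1] for b in resp.branches]
        assert psi[0] < math.pi / 2 - 0.1
        assert psi[1] == pytest.approx(math.pi / 2, abs=1e-6)
        assert psi[2] > math.pi / 2 + 0.1

    def test_hardening_peak_shifts_up_with_drive(self):
        omega = 2 * math.pi * np.linspace(350, 1400, 4001)
        peaks = []
        for scale in (0.5, 2.0, 8.0):
            p = DuffingParams(J_b=P_WEAK.J_b, c_amT=P_WEAK.c_amT,
                              k_lin=P_WEAK.k_lin, alpha_b=P_WEAK.alpha_b,
                              B=scale * P_WEAK.B)
            amp = ritz_response(p, omega).sweep_up()
            w_pk, _ = gs.peak_location(omega, amp)
            peaks.append(w_pk)
        assert peaks[0] < peaks[1] < peaks[2]

    def test_branch_counts_one_three_one(self):
        """Strong hardening: the branch count transitions 1 -> 3 -> 1 across
        the fold region, with the middle branch flagged unstable."""
        p = DuffingParams(J_b=P_WEAK.J_b, c_amT=P_WEAK.c_amT,
                          k_lin=P_WEAK.k_lin, alpha_b=P_WEAK.alpha_b,
                          B=30 * P_WEAK.B)
        omega = 2 * math.pi * np.linspace(400, 3000, 3001)
        resp = ritz_response(p, omega)
        counts = np.array([len(b) for b in resp.branches])
        assert set(counts) == {1, 3}
        changes = np.flatnonzero(np.diff(counts))
        assert len(changes) == 2  # one entry into and one exit from the fold
        for brs in resp.branches:
            if len(brs) == 3:
                assert [b[2] for b in brs] == [True, False, True]

    def test_peak_bounded_by_damping_limit(self):
        omega = 2 * math.pi * np.linspace(350, 1200, 6001)
        amp = ritz_response(P_WEAK, omega).sweep_up()
        w_pk, c_pk = gs.peak_location(omega, amp)
        assert c_pk <= P_WEAK.B / (P_WEAK.c_amT * w_pk) * 1.01

    def test_grid_outside_validity_rejected(self):
        with pytest.raises(ValueError):
            ritz_response(P_LIN, np.array([20.0 * P_LIN.omega_n]))


class TestTimeDomainOracle:
    def test_ritz_matches_integration_weak_nonlinearity(self):
        for w in (0.9, 1.0, 1.1):
            omega = w * math.sqrt(P_WEAK.k_lin / P_WEAK.J_b)
            ritz = ritz_response(P_WEAK, np.array([omega])).sweep_up()[0]
            direct = gs.steady_state_amplitude(P_WEAK, omega, n_periods=150)
            assert direct == pytest.approx(ritz, rel=0.02)

    def test_ringdown_decrement(self):
        """Free decay envelope: θ ~ exp(-c t / 2J)."""
        p = DuffingParams(J_b=5.86e-15, c_amT=2e-13, k_lin=4.9557e-8,
                          alpha_b=0.0, B=0.0)
        t, th, _ = time_integrate(p, omega=0.0, n_periods=60, theta0=1e-4)
        peaks_idx = [i for i in range(1, len(th) - 1)
                     if th[i] > th[i - 1] and th[i] > th[i + 1] and th[i] > 0]
        tp, ap = t[peaks_idx], th[peaks_idx]
        rate = -np.polyfit(tp, np.log(ap), 1)[0]
        assert rate == pytest.approx(p.c_amT / (2 * p.J_b), rel=0.01)

    def test_ringdown_frequency_matches_lumped_formula(self):
        p = DuffingParams(J_b=5.86e-15, c_amT=1e-14, k_lin=4.9557e-8,
                          alpha_b=0.0, B=0.0)
        t, th, _ = time_integrate(p, omega=0.0, n_periods=40, theta0=1e-4)
        # count zero crossings to get the oscillation frequency
        crossings = np.flatnonzero(np.diff(np.signbit(th)))
        f_ring = 0.5 * (len(crossings) - 1) / (t[crossings[-1]] - t[crossings[0]])
        assert f_ring == pytest.approx(
            gs.resonant_frequency(p.k_lin, p.J_b), rel=5e-3)

    def test_energy_conserved_undriven_undamped(self):
        p = DuffingParams(J_b=5.86e-15, c_amT=0.0, k_lin=4.9557e-8,
                          alpha_b=0.01, B=0.0)
        t, th, thd = time_integrate(p, omega=0.0, n_periods=20, theta0=2e-4,
                                    rtol=1e-11, atol=1e-14)
        E = 0.5 * p.J_b * thd**2 + 0.5 * p.k_lin * th**2 + 0.25 * p.alpha_b * th**4
        assert np.ptp(E) / E[0] < 1e-7

    def test_energy_balance_steady_cycle(self):
        """Work in equals heat out over one settled forcing period."""
        omega = math.sqrt(P_WEAK.k_lin / P_WEAK.J_b)
        t, th, thd = time_integrate(P_WEAK, omega, n_periods=200)
        T = 2 * math.pi / omega
        sel = t >= t[-1] - T
        ts, ths, thds = t[sel], th[sel], thd[sel]
        work = np.trapezoid(P_WEAK.B * np.sin(omega * ts) * thds, ts)
        heat = np.trapezoid(P_WEAK.c_amT * thds**2, ts)
        assert work == pytest.approx(heat, rel=5e-3)


class TestQualityFactor:
    def test_linear_limit_closed_form(self):
        omega = 2 * math.pi * np.linspace(300, 650, 2001)
        q = gs.quality_factor(ritz_response(P_LIN, omega))
        expected = math.sqrt(P_LIN.J_b * P_LIN.k_lin) / P_LIN.c_amT
        assert q == pytest.approx(expected, rel=0.01)

    def test_presets_order_frequency_and_quality(self, paper_scenario):
        """Stiffer gripped cells raise both the peak frequency and Q."""
        results = []
        for preset in ("cell_LNCaP", "cell_PC3", "cell_BHP"):
            scn = gs.load_scenario(preset)
            p = gs.assemble_motion_equation(scn)
            omega = gs.frequency_grid(scn)
            resp = ritz_response(p, omega)
            w_pk, _ = gs.peak_location(omega, resp.sweep_up())
            results.append((w_pk, gs.quality_factor(resp)))
        freqs, qs = zip(*results)
        assert freqs[0] < freqs[1] < freqs[2]
        assert qs[0] < qs[1] < qs[2]

    def test_peak_at_grid_edge_reported(self):
        omega = 2 * math.pi * np.linspace(600, 900, 101)  # peak below grid
        with pytest.raises(ValueError, match="grid"):
            gs.quality_factor(ritz_response(P_LIN, omega))
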