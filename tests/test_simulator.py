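import numpy as np
import pytest

from refillsim import (ParameterRegistry, SessionProtocol, VirtualPatient,
                       build_model, distribute_overload, run_session,
                       scenario_protocols, solve_initial_steady_state)
from refillsim.microvascular import interstitial_pressure, lymph_flow
from refillsim.simulator import (I_VIC, I_VIS, SL_BLOOD, SL_MIS, SL_MPL,
                                 N_STATE)


class TestInitialization:
    def test_overload_split_proportional(self, patient):
        v_pl, v_is = distribute_overload(patient)
        assert v_pl == pytest.approx(3500.0)   # +0.5 L plasma
        assert v_is == pytest.approx(17500.0)  # +2.5 L interstitium

    def test_zero_overload(self, registry):
        pat = VirtualPatient(registry.perturbed("fluid_overload", 0.0))
        v_pl, v_is = distribute_overload(pat)
        assert (v_pl, v_is) == (pytest.approx(3000.0), pytest.approx(15000.0))

    def test_overload_proportionality(self, registry):
        pat = VirtualPatient(ParameterRegistry({"fluid_overload": 1.8}))
        v_pl, v_is = distribute_overload(pat)
        assert v_pl - 3000.0 == pytest.approx(300.0)
        assert v_is - 15000.0 == pytest.approx(1500.0)

    def test_steady_state_balances_filtration_and_lymph(self, flatline_model):
        """R(0) = 0: total filtration equals lymph at the solved P_c,0."""
        f = flatline_model._fluxes(0.0, flatline_model.y_pre)
        assert f["j_v"].sum() == pytest.approx(f["q_l"], abs=1e-9)
        assert f["q_l"] == pytest.approx(6.55, abs=0.15)  # overloaded lymph

    def test_perturbed_lps_resolves_new_pc0_same_balance(self, registry):
        _, pc0_base = solve_initial_steady_state(VirtualPatient(registry))
        reg = registry.perturbed("lps", 8.0 / 6.0)
        pat = VirtualPatient(reg)
        m = __import__("refillsim").build_model(
            pat, SessionProtocol.flatline())
        assert m.pc0 != pytest.approx(pc0_base, abs=1e-6)
        f = m._fluxes(0.0, m.y_pre)
        assert f["j_v"].sum() == pytest.approx(f["q_l"], abs=1e-9)

    def test_full_state_residual(self, flatline_model):
        dy = flatline_model.rhs(0.0, flatline_model.y_pre)
        assert np.abs(dy).max() < 1e-9

    def test_interstitial_protein_near_configured_albumin_fraction(
            self, flatline_model):
        """The emergent interstitial albumin fraction sits near the
        configured 0.6 and total interstitial protein is physiological."""
        y = flatline_model.y_pre
        a_is = y[SL_MIS][0] / y[SL_MIS].sum()
        assert 0.5 < a_is < 0.75
        u = flatline_model.unpack(y)
        assert 2.0 < u["c_tp_is"] < 5.5  # g/dL, free-fluid concentration


class TestConservationLedgers:
    def test_water_ledger(self, basal):
        """Body water plus cumulative ultrafiltrate is constant."""
        # v_blood already includes the extracorporeal circuit
        tbw = basal["v_blood"] + basal["v_is"] + basal["v_ic"]
        cum_uf = basal.protocol.uf_rate * basal.times
        dev = (tbw + cum_uf) - tbw[0]
        assert np.abs(dev).max() <= 0.1  # mL over the whole session

    def test_protein_ledger(self, basal):
        """No dialyzer protein loss: total albumin+globulin mass constant."""
        m = basal.model
        # recompute from stored concentrations: c_tp * v_plasma + interstitium
        total = (basal["c_tp"] / 100.0 * basal["v_plasma"]
                 + basal["c_tp_is"] / 100.0
                 * (basal["v_is"] - m.patient.v_is_excluded))
        assert np.abs(total - total[0]).max() <= 1e-6

    def test_electroneutrality_of_adjusted_fluxes(self, basal):
        """Net transcapillary and dialyzer charge fluxes vanish."""
        m = basal.model
        for t in (0.0, 60.0, 180.0):
            k = np.searchsorted(basal.times, t)
            y = _state_at(basal, k)
            f = m._fluxes(basal.times[k], y)
            cap = np.dot(m.z_s, f["j_sol"]) + float(m.z_molar_p @ f["j_prot"])
            dial = np.dot(m.z_s, f["j_dial"])
            assert abs(cap) <= 1e-12
            assert abs(dial) <= 1e-12


def _state_at(traj, k):
    """Reconstruct an approximate state vector at sample k by re-running is
    unnecessary; re-simulate instead."""
    # states are not stored in the frame; rerun to the sample time
    from scipy.integrate import solve_ivp
    m = traj.model
    t = traj.times[k]
    if t == 0.0:
        return m.y0
    res = solve_ivp(m.rhs, (0.0, t), m.y0, method="LSODA", rtol=1e-8,
                    atol=1e-9 * np.maximum(np.abs(m.y0), 1.0))
    return res.y[:, -1]


class TestSessionBehavior:
    def test_flatline_preserves_equilibrium(self, flatline):
        """No UF, no priming: every series stays within 0.1 % for 300 min."""
        for col in flatline.data.columns:
            x = flatline[col]
            if col == "t" or abs(x[0]) < 1e-9:
                continue
            assert np.abs(x / x[0] - 1.0).max() < 1e-3, col

    def test_basal_blood_volume_declines_after_onset(self, basal):
        rbv = basal["rbv"]
        i10 = np.searchsorted(basal.times, 10.0)
        assert np.all(np.diff(rbv[i10:]) < 0)
        assert rbv[-1] < 97.0

    def test_end_state_matches_lymph_and_pressure_laws(self, basal):
        """Derived series are recomputable from the state columns."""
        m = basal.model
        p = interstitial_pressure(basal["v_is"][-1], m.lymph)
        assert p == pytest.approx(basal["p_is"][-1], abs=1e-9)
        assert lymph_flow(p, m.lymph) == pytest.approx(
            basal["q_lymph"][-1], abs=1e-9)

    def test_solver_tolerance_robustness(self, patient, basal):
        tight = run_session(patient, SessionProtocol(), rtol=5e-9)
        rel = abs(tight["v_plasma"][-1] - basal["v_plasma"][-1]) \
            / basal["v_plasma"][-1]
        assert rel < 1e-4  # halving tolerances moves end V_p by < 0.01 %

    def test_infused_recovery_settles_within_the_hour(self, trajectories):
        """After saline priming with no UF or dialysis, plasma volume needs
        tens of minutes to return toward the steady state: still >10 % of
        the initial displacement at 15 min, but <10 % by 60 min."""
        tr = trajectories("recovery", SessionProtocol(
            priming="infused", uf_total=0.0, urea_clearance=0.0,
            duration=120.0))
        vp = tr["v_plasma"]
        disp = vp - vp[-1]
        i15 = np.searchsorted(tr.times, 15.0)
        i60 = np.searchsorted(tr.times, 60.0)
        assert abs(disp[i15]) > 0.10 * abs(disp[0])
        assert abs(disp[i60]) < 0.10 * abs(disp[0])


class TestScenarioBattery:
    def test_battery_names(self):
        protocols = scenario_protocols()
        assert len(protocols) == 12
        assert {"basal", "lps4", "lps8", "lps_ramp_down", "lps_ramp_up",
                "dur180", "dur300", "uf10", "uf15", "infused_basal",
                "infused_lps4", "infused_lps8"} == set(protocols)

    def test_ramps_start_at_basal_lps(self):
        protocols = scenario_protocols()
        assert protocols["lps_ramp_down"].lps_profile(0.0) == 6.0
        assert protocols["lps_ramp_up"].lps_profile(0.0) == 6.0

    def test_discarded_scenarios_share_pre_dialysis_state(self, patient):
        m1 = build_model(patient, scenario_protocols()["basal"])
        m2 = build_model(patient, scenario_protocols()["uf15"])
        np.testing.assert_allclose(m1.y_pre, m2.y_pre, rtol=1e-12)

    def test_state_vector_layout(self, flatline_model):
        assert flatline_model.y_pre.shape == (N_STATE,)
        assert np.all(flatline_model.y_pre[SL_BLOOD] > 0)
        assert flatline_model.y_pre[I_VIS] == pytest.approx(17500.0)
        assert flatline_model.y_pre[I_VIC] == pytest.approx(23000.0)
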