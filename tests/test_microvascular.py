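import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refillsim import microvascular as mv

LYMPH = mv.InterstitiumLymphParams()
PORES = mv.PoreSystem()


class TestOncoticPressures:
    @pytest.mark.parametrize("c,a,expected", [
        (0.0, 0.6, 0.0),
        (7.0, 0.6, 0.6 * (19.6 + 8.82 + 4.116)),   # 19.52 mmHg
        (7.0, 1.0, 32.536),                        # pure-albumin limit
    ])
    def test_albumin_polynomial(self, c, a, expected):
        assert mv.pi_albumin(c, a) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("c,a,expected", [
        (0.0, 0.6, 0.0),
        (7.0, 0.6, 0.4 * (7.7 + 6.37 + 1.715)),    # 6.31 mmHg
        (7.0, 1.0, 0.0),                           # no globulin
    ])
    def test_globulin_polynomial(self, c, a, expected):
        assert mv.pi_globulin(c, a) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("c,expected", [
        (0.0, 0.0),
        (7.0, 14.7 + 7.84 + 3.087),                # 25.63 mmHg
    ])
    def test_landis_pappenheimer(self, c, expected):
        assert mv.pi_total_landis_pappenheimer(c) == pytest.approx(expected)

    @pytest.mark.parametrize("fn", [mv.pi_albumin, mv.pi_globulin])
    def test_negative_concentration_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(-1.0, 0.6)
        with pytest.raises(ValueError):
            mv.pi_total_landis_pappenheimer(-0.1)

    @given(st.floats(min_value=4.0, max_value=9.0))
    @settings(deadline=None, max_examples=50)
    def test_fraction_sum_matches_landis_pappenheimer(self, c):
        """At the normal A/G ratio (a = 0.6) the two-fraction split
        reproduces the total-protein law within 1 %."""
        total = mv.pi_albumin(c, 0.6) + mv.pi_globulin(c, 0.6)
        lp = mv.pi_total_landis_pappenheimer(c)
        assert total == pytest.approx(lp, rel=0.01)


class TestPressuresAndLymph:
    def test_capillary_pressure_reference_point(self):
        assert mv.capillary_pressure(12.0, p_c0=17.3) == pytest.approx(17.3)

    @pytest.mark.parametrize("p_sv,expected", [(10.0, 13.4), (12.5, 15.4)])
    def test_capillary_pressure_linear(self, p_sv, expected):
        assert mv.capillary_pressure(p_sv, p_c0=15.0) == pytest.approx(expected)

    @pytest.mark.parametrize("v_is,expected", [
        (15000.0, -1.0),                   # normal volume
        (17500.0, -1.0 + 2500.0 / 1800.0),  # fluid-overloaded, ~0.39 mmHg
        (7500.0, -1.0 - 7500.0 / 1800.0),   # excluded volume, P_is,ex
    ])
    def test_interstitial_pressure(self, v_is, expected):
        assert mv.interstitial_pressure(v_is, LYMPH) == pytest.approx(expected)

    @pytest.mark.parametrize("p_is,expected", [
        (-1.0, 8000.0 / 1440.0),                     # Q_L,n = 5.556 mL/min
        (0.39, 8000.0 / 1440.0 + 43.1 / 60.0 * 1.39),  # ~6.55, overloaded
        (-0.8, 8000.0 / 1440.0 + 43.1 / 60.0 * 0.2),   # ~5.70, end of HD
        (LYMPH.p_is_excluded, 0.0),                  # cutoff
        (-10.0, 0.0),                                # below cutoff
    ])
    def test_lymph_flow_values(self, p_is, expected):
        assert mv.lymph_flow(p_is, LYMPH) == pytest.approx(expected, abs=1e-9)

    @given(st.floats(min_value=-8.0, max_value=4.0))
    @settings(deadline=None, max_examples=100)
    def test_lymph_flow_piecewise_linear_continuous(self, p):
        """Continuous, nonnegative, with the documented slopes on each branch."""
        q = mv.lymph_flow(p, LYMPH)
        assert q >= 0.0
        eps = 1e-6
        q_hi = mv.lymph_flow(p + eps, LYMPH)
        assert abs(q_hi - q) < 1e-4  # continuity
        if p > LYMPH.p_is_n:
            slope = (q_hi - q) / eps
            assert slope == pytest.approx(LYMPH.lymph_sensitivity, rel=1e-3)
        elif LYMPH.p_is_excluded < p < LYMPH.p_is_n - eps:
            slope = (q_hi - q) / eps
            expected = LYMPH.q_lymph_n / (LYMPH.p_is_n - LYMPH.p_is_excluded)
            assert slope == pytest.approx(expected, rel=1e-3)
        elif p < LYMPH.p_is_excluded - eps:
            assert q == 0.0


class TestPoreFluxes:
    def test_equilibrium_gives_zero_everywhere(self):
        sig = np.ones((3, 2))
        for i in range(3):
            j = mv.pore_fluid_flux(i, 10.0, 10.0, [20.0, 5.0], [20.0, 5.0],
                                   sig, PORES)
            assert j == pytest.approx(0.0)

    def test_small_pore_absorption(self):
        # sigma = 1 for both fractions, pi gradient 14.0 vs dP 13.8
        sig = np.ones((3, 2))
        j = mv.pore_fluid_flux(1, 13.8, 0.0, [25.8, 0.0], [11.8, 0.0],
                               sig, PORES)
        assert j == pytest.approx(0.85 * 6.0 * (13.8 - 14.0))  # -1.02

    def test_aquaporin_small_solute_gradient_is_potent(self):
        # 1 mmol/L through the water-only pathway: 19.3 mmHg of drive
        sig_p = np.ones((3, 1))
        sig_s = np.ones((3, 1))
        j = mv.pore_fluid_flux(2, 0.0, 0.0, [0.0], [0.0], sig_p, PORES,
                               c_pl_water=[1.0], c_is_water=[0.0],
                               sigma_solute=sig_s, phi=[1.0])
        assert j == pytest.approx(-0.10 * 6.0 * 19.3)  # -11.58 mL/min

    def test_unknown_pore_index(self):
        with pytest.raises(IndexError):
            mv.pore_fluid_flux(3, 0, 0, [0], [0], np.ones((3, 1)), PORES)

    @pytest.mark.parametrize("pc,pis,pipl,piis,sig,kf,expected", [
        (14.0, 0.0, 14.2, 0.2, 1.0, 6.0, 0.0),     # Starling equilibrium
        (14.0, 0.0, 14.2, 0.0, 1.0, 6.0, -1.2),
        (2.0, 0.0, 30.0, 0.0, 0.0, 6.0, 12.0),     # purely hydraulic
    ])
    def test_classic_starling(self, pc, pis, pipl, piis, sig, kf, expected):
        assert mv.classic_starling_flux(pc, pis, pipl, piis, sig, kf) == \
            pytest.approx(expected)

    def test_aggregation_consistency(self):
        """Sum of per-pore fluxes equals the single-membrane law when all
        pores share one reflection coefficient and solutes are absent."""
        sigma = 0.7
        sig = np.full((3, 2), sigma)
        args = (16.0, 0.4, [19.5, 6.3], [8.0, 2.5])
        total = sum(mv.pore_fluid_flux(i, *args, sig, PORES) for i in range(3))
        classic = mv.classic_starling_flux(16.0, 0.4, 19.5 + 6.3, 8.0 + 2.5,
                                           sigma, PORES.lps)
        assert total == pytest.approx(classic, rel=1e-12)


class TestProteinAndSoluteFluxes:
    def test_no_flux_at_equilibrium(self):
        assert mv.protein_flux(0, 0.5, 1.0, 0.0, 0.05, 0.05) == 0.0

    def test_convection_with_mean_concentration(self):
        j = mv.protein_flux(0, 0.05, 0.0, 0.3, 0.05, 0.05)
        assert j == pytest.approx(0.95 * 0.3 * 0.05)  # 0.014 g/min

    def test_fully_reflected_protein_has_no_convection(self):
        assert mv.protein_flux(1, 1.0, 0.0, 5.0, 0.08, 0.02) == 0.0

    def test_no_protein_through_aquaporins(self):
        assert mv.protein_flux(2, 0.0, 10.0, 5.0, 0.08, 0.02) == 0.0

    def test_carrier_balances_cation_flux(self):
        # +0.2 mEq/min net cation flux, carrier valence -2
        fluxes = np.array([0.2, 0.0, 0.0])
        z = np.array([+1.0, 0.0, -2.0])
        adj = mv.electroneutrality_adjustment(fluxes, z, carrier=2)
        assert adj[2] == pytest.approx(0.1)          # same direction
        assert np.dot(z, adj) == pytest.approx(0.0, abs=1e-15)

    def test_uncharged_solutes_unaffected(self):
        fluxes = np.array([0.2, 3.5, 0.0])
        z = np.array([+1.0, 0.0, -2.0])
        adj = mv.electroneutrality_adjustment(fluxes, z, carrier=2)
        assert adj[1] == fluxes[1]                   # urea untouched

    def test_zero_fluxes_give_zero_carrier(self):
        adj = mv.electroneutrality_adjustment(
            np.zeros(3), np.array([1.0, -1.0, -2.0]), carrier=2)
        assert adj[2] == 0.0

    def test_carrier_must_be_charged(self):
        with pytest.raises(ValueError):
            mv.electroneutrality_adjustment(
                np.zeros(2), np.array([1.0, 0.0]), carrier=1)

    @given(st.floats(min_value=-2.0, max_value=2.0),
           st.floats(min_value=-2.0, max_value=2.0),
           st.floats(min_value=-0.5, max_value=0.5))
    @settings(deadline=None, max_examples=50)
    def test_adjusted_charge_flux_always_zero(self, f1, f2, extra):
        z = np.array([1.0, -1.0, -2.0])
        adj = mv.electroneutrality_adjustment(np.array([f1, f2, 0.0]), z, 2,
                                              extra_charge_flux=extra)
        assert abs(np.dot(z, adj) + extra) <= 1e-12


class TestReflectionCoefficients:
    def test_full_reflection_beyond_pore_size(self):
        assert mv.reflection_coefficient(52.0, 45.0) == 1.0

    def test_ordering_small_pore(self):
        """Albumin nearly reflected, small ions nearly free in small pores."""
        s_alb = mv.reflection_coefficient(35.5, 45.0)
        s_urea = mv.reflection_coefficient(2.6, 45.0)
        s_na = mv.reflection_coefficient(1.8, 45.0)
        assert 0.85 < s_alb < 1.0
        assert s_na < s_urea < 0.05

    def test_pore_system_invariants(self):
        with pytest.raises(ValueError):
            mv.PoreSystem(alphas=(0.1, 0.8, 0.2))
        with pytest.raises(ValueError):
            mv.PoreSystem(lps=-1.0)
        assert PORES.sigma_protein(35.5)[2] == 1.0   # aquaporins water-only


class TestTypeInvariants:
    def test_interstitium_params_validation(self):
        with pytest.raises(ValueError):
            mv.InterstitiumLymphParams(compliance=-1.0)
        with pytest.raises(ValueError):
            mv.InterstitiumLymphParams(v_is_excluded=16000.0)

    def test_protein_fraction_validation(self):
        with pytest.raises(ValueError):
            mv.ProteinFraction("albumin", -1.0, 0.0, 0.6, 0.6,
                               np.array([0.5]), np.array([0.1]))
        with pytest.raises(ValueError):
            mv.ProteinFraction("albumin", 1.0, 1.0, 1.5, 0.6,
                               np.array([0.5]), np.array([0.1]))

    def test_small_solute_validation(self):
        with pytest.raises(ValueError):
            mv.SmallSolute("na", 1, 0.93, -1.0, 0.0, 0.0, np.array([0.5]))
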