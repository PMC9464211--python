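"""Steady-state initialization, full ODE assembly and scenario execution.

The state vector couples the nine-compartment circulation with whole-body
fluid and solute kinetics:

* blood volumes of the nine vascular compartments (mL),
* interstitial and intracellular water volumes (mL),
* albumin and globulin masses in plasma and interstitium (g),
* seven small-solute amounts in plasma, interstitial and cell water (mmol),
* four baroreflex controller outputs.

The forward model is fully deterministic.  The virtual patient is
initialized in a fluid-overloaded pre-dialysis steady state: the overload is
split between plasma and interstitium proportionally to their normal
volumes, normal pressures are anchored at that state, and the initial mean
capillary pressure plus the interstitial protein masses are solved so that
total transcapillary filtration equals lymph flow and the capillary protein
leak equals the lymphatic protein return.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from . import circulation, microvascular, units
from .dialysis import SALINE_CL, SALINE_NA, SessionProtocol
from .params import COMPARTMENTS, PORES, SOLUTES, ParameterRegistry, VirtualPatient

# --- state vector layout ---------------------------------------------------
N_COMP = len(COMPARTMENTS)
N_SOL = len(SOLUTES)
SL_BLOOD = slice(0, N_COMP)
I_VIS = N_COMP
I_VIC = N_COMP + 1
SL_MPL = slice(N_COMP + 2, N_COMP + 4)     # albumin, globulin in plasma (g)
SL_MIS = slice(N_COMP + 4, N_COMP + 6)
SL_NPL = slice(N_COMP + 6, N_COMP + 6 + N_SOL)
SL_NIS = slice(N_COMP + 6 + N_SOL, N_COMP + 6 + 2 * N_SOL)
SL_NIC = slice(N_COMP + 6 + 2 * N_SOL, N_COMP + 6 + 3 * N_SOL)
SL_BARO = slice(N_COMP + 6 + 3 * N_SOL, N_COMP + 10 + 3 * N_SOL)
N_STATE = N_COMP + 10 + 3 * N_SOL

I_CAP = COMPARTMENTS.index("capillaries")
I_SV = COMPARTMENTS.index("small_veins")
I_LV = COMPARTMENTS.index("large_veins")
I_LA = COMPARTMENTS.index("large_arteries")
I_RH = COMPARTMENTS.index("right_heart")
I_LH = COMPARTMENTS.index("left_heart")
CARRIER = SOLUTES.index("other_anions")


def distribute_overload(patient: VirtualPatient) -> tuple[float, float]:
    """Split the fluid overload between plasma and interstitium.

    Proportional to their normal volumes; returns the pre-dialysis plasma
    and interstitial volumes in mL.
    """
    share_pl = patient.v_plasma_n / (patient.v_plasma_n + patient.v_is_n)
    v_pl = patient.v_plasma_n + patient.overload * share_pl
    v_is = patient.v_is_n + patient.overload * (1.0 - share_pl)
    return v_pl, v_is


@dataclasses.dataclass
class Model:
    """Patient + protocol compiled to flat arrays plus the assembled RHS."""

    patient: VirtualPatient
    protocol: SessionProtocol

    # populated by ``build``
    compliances: np.ndarray = None
    unstressed: np.ndarray = None
    resistances: np.ndarray = None
    pump_gains: tuple[float, float] = None
    baro: circulation.BaroreflexParams = None
    lymph: microvascular.InterstitiumLymphParams = None
    sigma_p: np.ndarray = None       # (3, 2)
    ps_p: np.ndarray = None          # (3, 2)
    sigma_s: np.ndarray = None       # (3, 7)
    phi: np.ndarray = None
    z_s: np.ndarray = None
    ps_s: np.ndarray = None
    ps_cell: np.ndarray = None
    sigma_cell: np.ndarray = None
    z_molar_p: np.ndarray = None     # mEq per g of protein
    clearances: np.ndarray = None
    alpha_d: np.ndarray = None
    c_dialysate: np.ndarray = None
    donnan_offset: np.ndarray = None
    alphas: np.ndarray = None
    pc0: float = 0.0
    p_sv0: float = 0.0
    v_rbc: float = 0.0
    v_circ: float = 0.0
    lp_cell: float = 0.0
    w_v: float = 0.8
    f_water_slope: float = 0.0       # (1 - F_n) / C_tp_n, per g/dL
    y0: np.ndarray = None
    y_pre: np.ndarray = None         # pre-priming steady state

    # ------------------------------------------------------------------
    def lps(self, t: float) -> float:
        return self.protocol.lps_profile(t, default=self.patient.registry["lps"])

    def uf(self, t: float) -> float:
        if self.protocol.uf_total == 0.0:
            return 0.0
        return self.protocol.uf_rate if t <= self.protocol.duration else 0.0

    # ------------------------------------------------------------------
    def unpack(self, y: np.ndarray) -> dict:
        r = self.patient.registry
        v_blood = y[SL_BLOOD]
        total_blood = v_blood.sum() + self.v_circ
        v_plasma = total_blood - self.v_rbc
        m_pl, m_is = y[SL_MPL], y[SL_MIS]
        c_tp = m_pl.sum() / v_plasma * 100.0          # g/dL
        # interstitial proteins are excluded from part of the matrix; their
        # effective (free-fluid) concentration uses the available volume
        v_is_avail = y[I_VIS] - self.patient.v_is_excluded
        c_tp_is = m_is.sum() / v_is_avail * 100.0
        f_pl = 1.0 - self.f_water_slope * c_tp
        return dict(v_blood=v_blood, v_plasma=v_plasma, v_is=y[I_VIS],
                    v_is_avail=v_is_avail, v_ic=y[I_VIC], m_pl=m_pl,
                    m_is=m_is, c_tp=c_tp, c_tp_is=c_tp_is, f_pl=f_pl,
                    hct=self.v_rbc / total_blood, total_blood=total_blood)

    # ------------------------------------------------------------------
    def _fluxes(self, t: float, y: np.ndarray):
        """All instantaneous pressures and fluxes (shared by RHS and output)."""
        u = self.unpack(y)
        v_blood, v_plasma, v_is = u["v_blood"], u["v_plasma"], u["v_is"]
        baro = y[SL_BARO]

        # circulation pressures; baroreflex shifts the small-vein unstressed volume
        vu = self.unstressed.copy()
        vu[I_SV] += baro[3]
        pressures = (v_blood - vu) / self.compliances

        # transcapillary pressures and oncotic pressures
        p_sv = pressures[I_SV]
        p_c = self.pc0 + self.w_v * (p_sv - self.p_sv0)
        p_is = microvascular.interstitial_pressure(v_is, self.lymph)
        q_l = microvascular.lymph_flow(p_is, self.lymph)

        a_pl = u["m_pl"][0] / u["m_pl"].sum()
        a_is = u["m_is"][0] / u["m_is"].sum()
        pi_pl = np.array([microvascular.pi_albumin(u["c_tp"], a_pl),
                          microvascular.pi_globulin(u["c_tp"], a_pl)])
        pi_is = np.array([microvascular.pi_albumin(u["c_tp_is"], a_is),
                          microvascular.pi_globulin(u["c_tp_is"], a_is)])

        # solute concentrations per litre of water
        c_plw = y[SL_NPL] / (v_plasma * u["f_pl"]) * 1000.0
        c_isw = y[SL_NIS] / v_is * 1000.0
        c_icw = y[SL_NIC] / y[I_VIC] * 1000.0

        # per-pore fluid flux
        kf = self.lps(t)
        dpi = self.sigma_p @ (pi_pl - pi_is)
        osm = (self.sigma_s * self.phi) @ (c_plw - c_isw - self.donnan_offset) \
            * units.RT_MMHG_PER_MMOL_L
        j_v = self.alphas * kf * ((p_c - p_is) - dpi - osm)

        # protein fluxes, plasma -> interstitium (g/min); interstitial side
        # at the free-fluid (excluded-volume-corrected) concentration
        c_p_pl = u["m_pl"] / v_plasma
        c_p_is = u["m_is"] / u["v_is_avail"]
        c_p_mean = 0.5 * (c_p_pl + c_p_is)
        j_prot = ((1.0 - self.sigma_p) * j_v[:, None] * c_p_mean[None, :]
                  + self.ps_p * (c_p_pl - c_p_is)[None, :]).sum(axis=0)

        # small-solute capillary fluxes with electroneutrality carrier
        c_s_mean = 0.5 * (c_plw + c_isw)
        conv = ((1.0 - self.sigma_s) * j_v[:, None]).sum(axis=0)
        j_sol = (conv * c_s_mean + self.ps_s * (c_plw - c_isw)) / 1000.0
        prot_charge_flux = float(self.z_molar_p @ j_prot)
        j_sol = microvascular.electroneutrality_adjustment(
            j_sol, self.z_s, CARRIER, extra_charge_flux=prot_charge_flux)

        # lymph return (bulk interstitial fluid)
        lymph_prot = q_l * c_p_is
        lymph_sol = q_l * c_isw / 1000.0

        # cell membrane exchange
        osm_gap = float(self.phi * self.sigma_cell @ (c_isw - c_icw))
        j_w_cell = self.lp_cell * units.RT_MMHG_PER_MMOL_L * osm_gap
        j_sol_cell = self.ps_cell * (c_isw - c_icw) / 1000.0

        # dialyzer
        active = (self.protocol.blood_flow > 0.0) and (t <= self.protocol.duration)
        if active:
            j_dial = self.clearances * (self.alpha_d * c_plw - self.c_dialysate) \
                / 1000.0
            j_dial = microvascular.electroneutrality_adjustment(
                j_dial, self.z_s, CARRIER)
            uf = self.uf(t)
            q_b = self.protocol.blood_flow
        else:
            j_dial = np.zeros(N_SOL)
            uf = 0.0
            q_b = 0.0

        return dict(u=u, pressures=pressures, p_c=p_c, p_is=p_is, q_l=q_l,
                    pi_pl=pi_pl, pi_is=pi_is, osm=osm, j_v=j_v, j_prot=j_prot,
                    j_sol=j_sol, lymph_prot=lymph_prot, lymph_sol=lymph_sol,
                    j_w_cell=j_w_cell, j_sol_cell=j_sol_cell, j_dial=j_dial,
                    uf=uf, q_b=q_b, baro=y[SL_BARO], c_plw=c_plw, c_isw=c_isw,
                    c_icw=c_icw, kf=kf, a_pl=a_pl, a_is=a_is)

    # ------------------------------------------------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        f = self._fluxes(t, y)
        p = f["pressures"]
        baro = f["baro"]

        flows = circulation.vascular_flows(
            p, self.resistances, self.pump_gains,
            pump_scaling=baro[0] * baro[1], resistance_scaling=baro[2])

        dy = np.zeros(N_STATE)
        dv = dy[SL_BLOOD]
        for i in range(N_COMP):
            upstream = (i - 1) % N_COMP
            dv[i] = flows[upstream] - flows[i]
        j_v_tot = f["j_v"].sum()
        dv[I_CAP] += -j_v_tot
        dv[I_LV] += f["q_l"]
        dv[I_LA] += -f["q_b"]
        dv[I_SV] += f["q_b"] - f["uf"]

        dy[I_VIS] = j_v_tot - f["q_l"] + f["j_w_cell"]
        dy[I_VIC] = -f["j_w_cell"]

        dy[SL_MPL] = -f["j_prot"] + f["lymph_prot"]
        dy[SL_MIS] = f["j_prot"] - f["lymph_prot"]

        dy[SL_NPL] = -f["j_sol"] + f["lymph_sol"] - f["j_dial"]
        dy[SL_NIS] = f["j_sol"] - f["lymph_sol"] - f["j_sol_cell"]
        dy[SL_NIC] = f["j_sol_cell"]

        dy[SL_BARO] = circulation.baroreflex_derivative(
            baro, self.baro, p[I_LA], p[I_RH])
        return dy

    def circulation_rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Time derivatives of the nine blood-compartment volumes only."""
        return self.rhs(t, y)[SL_BLOOD]


# ---------------------------------------------------------------------------
# model construction and steady-state initialization
# ---------------------------------------------------------------------------

def build_model(patient: VirtualPatient,
                protocol: SessionProtocol | None = None) -> Model:
    """Assemble arrays, solve the pre-dialysis steady state and apply priming."""
    protocol = protocol or SessionProtocol()
    r = patient.registry
    m = Model(patient=patient, protocol=protocol)

    # --- fluid spaces ---
    v_plasma0, v_is0 = distribute_overload(patient)
    v_ic0 = patient.v_ic_n
    m.v_rbc = patient.v_rbc
    blood0 = v_plasma0 + m.v_rbc

    # --- circulation anchored at the overloaded normal-pressure state ---
    frac = patient.compartment_fractions()
    v_comp0 = frac * blood0
    m.compliances = patient.compartment_compliances()
    p_n = patient.compartment_pressures_normal()
    m.unstressed = v_comp0 - m.compliances * p_n
    co = patient.cardiac_output_n
    m.pump_gains = (co / p_n[I_RH], co / p_n[I_LH])
    m.baro = circulation.BaroreflexParams.from_patient(
        patient, set_point_arterial=p_n[I_LA], set_point_cardiopulmonary=p_n[I_RH])

    # --- interstitium and lymph ---
    m.lymph = microvascular.InterstitiumLymphParams(
        p_is_n=r["p_is_normal"], v_is_n=patient.v_is_n,
        compliance=patient.c_is_compliance, q_lymph_n=patient.q_lymph_n,
        lymph_sensitivity=patient.lymph_sensitivity,
        v_is_excluded=patient.v_is_excluded)
    p_is0 = microvascular.interstitial_pressure(v_is0, m.lymph)
    q_l0 = microvascular.lymph_flow(p_is0, m.lymph)

    # steady-state link flows carry the lymph loop: capillaries lose the
    # filtrate, large veins recover it as lymph
    q_links = np.full(len(circulation.PASSIVE_LINKS), co)
    for k, (up, _) in enumerate(circulation.PASSIVE_LINKS):
        if up in ("capillaries", "small_veins"):
            q_links[k] = co - q_l0
    m.resistances = np.empty(len(circulation.PASSIVE_LINKS))
    for k, (up, dn) in enumerate(circulation.PASSIVE_LINKS):
        dp = p_n[circulation.IDX[up]] - p_n[circulation.IDX[dn]]
        if dp <= 0:
            raise ValueError(f"non-positive normal pressure drop on {up}->{dn}")
        m.resistances[k] = dp / q_links[k]

    # --- pore system ---
    kf0 = protocol.lps_profile(0.0, default=r["lps"])
    pores = microvascular.PoreSystem(
        radii=(r["r_pore_large"], r["r_pore_small"], r["r_pore_ultrasmall"]),
        alphas=(r["alpha_large"], r["alpha_small"], r["alpha_ultrasmall"]),
        lps=kf0)
    m.alphas = np.array(pores.alphas)
    m.sigma_p = np.stack([pores.sigma_protein(r["r_albumin"]),
                          pores.sigma_protein(r["r_globulin"])], axis=1)
    m.ps_p = np.array([[r["ps_albumin_large"], r["ps_globulin_large"]],
                       [r["ps_albumin_small"], r["ps_globulin_small"]],
                       [0.0, 0.0]])
    m.sigma_s = np.stack([pores.sigma_solute(r[f"{s}_radius"]) for s in SOLUTES],
                         axis=1)
    m.phi = np.array([r[f"{s}_phi"] for s in SOLUTES])
    m.z_s = np.array([r[f"{s}_valence"] for s in SOLUTES])
    m.ps_s = np.array([r[f"{s}_ps_capillary"] for s in SOLUTES])
    m.ps_cell = np.array([r[f"{s}_ps_cell"] for s in SOLUTES])
    m.sigma_cell = np.array([r[f"{s}_sigma_cell"] for s in SOLUTES])
    m.z_molar_p = np.array([r["z_albumin"] / r["mw_albumin"],
                            r["z_globulin"] / r["mw_globulin"]])
    m.lp_cell = r["lp_cell"]
    m.w_v = r["w_venous"]
    m.p_sv0 = r["p_sv_reference"]
    m.f_water_slope = (1.0 - r["f_plasma_water_normal"]) / r["total_protein_plasma"]

    # --- dialyzer ---
    m.clearances = np.array([protocol.urea_clearance * r[f"{s}_clearance_scale"]
                             for s in SOLUTES])
    m.clearances[CARRIER] = 0.0  # carrier flux set by charge balance
    m.alpha_d = np.array([r[f"{s}_alpha_dialyzer"] for s in SOLUTES])
    m.c_dialysate = np.array([r[f"{s}_dialysate"] for s in SOLUTES])

    # --- proteins: plasma pools and steady-state interstitial pools ---
    c_tp0 = r["total_protein_plasma"]
    a0 = r["albumin_fraction_plasma"]
    m_pl0 = np.array([a0, 1.0 - a0]) * units.g_per_dl(c_tp0) * v_plasma0
    v_is_avail0 = v_is0 - patient.v_is_excluded

    def residuals(x):
        pc0, m_alb_is, m_glob_is = x
        m_is = np.array([m_alb_is, m_glob_is])
        a_is = m_alb_is / m_is.sum()
        c_is = m_is.sum() / v_is_avail0 * 100.0
        pi_pl = np.array([microvascular.pi_albumin(c_tp0, a0),
                          microvascular.pi_globulin(c_tp0, a0)])
        pi_is = np.array([microvascular.pi_albumin(c_is, a_is),
                          microvascular.pi_globulin(c_is, a_is)])
        j_v = m.alphas * kf0 * ((pc0 - p_is0) - m.sigma_p @ (pi_pl - pi_is))
        c_p_pl = m_pl0 / v_plasma0
        c_p_is = m_is / v_is_avail0
        j_prot = ((1.0 - m.sigma_p) * j_v[:, None]
                  * (0.5 * (c_p_pl + c_p_is))[None, :]
                  + m.ps_p * (c_p_pl - c_p_is)[None, :]).sum(axis=0)
        return [j_v.sum() - q_l0,
                j_prot[0] - q_l0 * c_p_is[0],
                j_prot[1] - q_l0 * c_p_is[1]]

    a_is_guess = r["albumin_fraction_is"]
    guess = [p_is0 + q_l0 / kf0 + 15.0,
             0.4 * m_pl0.sum() * a_is_guess * v_is0 / v_plasma0,
             0.4 * m_pl0.sum() * (1 - a_is_guess) * v_is0 / v_plasma0]
    sol, info, ier, msg = fsolve(residuals, guess, full_output=True, xtol=1e-13)
    if ier != 1:
        raise RuntimeError(
            f"pre-dialysis steady state did not converge: {msg}; "
            f"last residuals {info['fvec']}")
    m.pc0 = float(sol[0])
    m_is0 = np.array(sol[1:])

    # --- small solutes ---
    f_pl0 = r["f_plasma_water_normal"]
    c_pl = np.array([r[f"{s}_plasma"] for s in SOLUTES])   # mmol/L plasma
    c_plw = c_pl / f_pl0
    # carrier from plasma electroneutrality (incl. protein charge)
    prot_gl_w = m_pl0 / (v_plasma0 * f_pl0) * 1000.0       # g/L water
    prot_charge = float(m.z_molar_p @ prot_gl_w)           # mEq/L water
    others = np.delete(np.arange(N_SOL), CARRIER)
    c_plw[CARRIER] = -(m.z_s[others] @ c_plw[others] + prot_charge) \
        / m.z_s[CARRIER]
    if c_plw[CARRIER] <= 0:
        raise RuntimeError("electroneutrality carrier concentration must be > 0")

    # interstitial concentrations from the solute steady state
    pi_pl0 = np.array([microvascular.pi_albumin(c_tp0, a0),
                       microvascular.pi_globulin(c_tp0, a0)])
    c_is_tot0 = m_is0.sum() / v_is_avail0 * 100.0
    a_is0 = m_is0[0] / m_is0.sum()
    pi_is0 = np.array([microvascular.pi_albumin(c_is_tot0, a_is0),
                       microvascular.pi_globulin(c_is_tot0, a_is0)])
    j_v0 = m.alphas * kf0 * ((m.pc0 - p_is0) - m.sigma_p @ (pi_pl0 - pi_is0))
    conv = ((1.0 - m.sigma_s) * j_v0[:, None]).sum(axis=0)
    c_isw = c_plw * (0.5 * conv + m.ps_s) / (q_l0 - 0.5 * conv + m.ps_s)
    prot_is_gl = m_is0 / v_is_avail0 * 1000.0   # free-fluid concentration
    prot_is_charge = float(m.z_molar_p @ prot_is_gl)
    c_isw[CARRIER] = -(m.z_s[others] @ c_isw[others] + prot_is_charge) \
        / m.z_s[CARRIER]
    m.donnan_offset = c_plw - c_isw

    # intracellular: permeant solutes equilibrated, filler solves osmolality
    c_icw = np.array([r[f"{s}_intracellular"] for s in SOLUTES])
    for i, s in enumerate(SOLUTES):
        if m.ps_cell[i] > 0:
            c_icw[i] = c_isw[i]
    osm_is = float(m.phi * m.sigma_cell @ c_isw)
    partial = float(np.delete(m.phi * m.sigma_cell, CARRIER)
                    @ np.delete(c_icw, CARRIER))
    c_icw[CARRIER] = (osm_is - partial) / (m.phi[CARRIER] * m.sigma_cell[CARRIER])
    if c_icw[CARRIER] <= 0:
        raise RuntimeError("intracellular osmotic balance needs a positive filler")

    # --- assemble pre-priming state ---
    y = np.zeros(N_STATE)
    y[SL_BLOOD] = v_comp0
    y[I_VIS] = v_is0
    y[I_VIC] = v_ic0
    y[SL_MPL] = m_pl0
    y[SL_MIS] = m_is0
    y[SL_NPL] = c_plw * v_plasma0 * f_pl0 / 1000.0
    y[SL_NIS] = c_isw * v_is0 / 1000.0
    y[SL_NIC] = c_icw * v_ic0 / 1000.0
    y[SL_BARO] = np.array([1.0, 1.0, 1.0, 0.0])
    m.y_pre = y.copy()

    m.v_circ = 0.0
    m.y0 = apply_priming(m, y)
    return m


def _quasi_steady_volumes(model: Model, total_volume: float,
                          sources: np.ndarray) -> np.ndarray:
    """Circulation volumes at steady flow for a given total in-body volume.

    The vascular loop equilibrates within seconds, far below the sampling
    grid, so states after an acute volume change (circuit filling) are taken
    as the steady-flow solution of the linear pressure/flow network with the
    baroreflex still neutral.  ``sources`` holds external inflows per
    compartment (lymph, transcapillary loss, access flows); they must sum to
    zero for a consistent steady loop.
    """
    if abs(sources.sum()) > 1e-9:
        raise ValueError("steady-loop sources must sum to zero")
    # link flow k = Q + cumulative source from large arteries through link k
    cum = np.cumsum(sources)
    n = N_COMP + 1  # unknowns: 9 volumes + base loop flow Q
    a = np.zeros((n, n))
    b = np.zeros(n)
    elast = 1.0 / model.compliances
    vu = model.unstressed
    row = 0
    for k, (up, dn) in enumerate(circulation.PASSIVE_LINKS):
        i, j = circulation.IDX[up], circulation.IDX[dn]
        a[row, i] = elast[i]
        a[row, j] = -elast[j]
        a[row, N_COMP] = -model.resistances[k]
        b[row] = model.resistances[k] * cum[i] + vu[i] * elast[i] \
            - vu[j] * elast[j]
        row += 1
    for idx, gain in ((I_RH, model.pump_gains[0]), (I_LH, model.pump_gains[1])):
        a[row, idx] = gain * elast[idx]
        a[row, N_COMP] = -1.0
        b[row] = cum[idx] + gain * vu[idx] * elast[idx]
        row += 1
    a[row, :N_COMP] = 1.0
    b[row] = total_volume
    x = np.linalg.solve(a, b)
    return x[:N_COMP]


def apply_priming(model: Model, y_pre: np.ndarray) -> np.ndarray:
    """Apply the priming procedure to the pre-dialysis steady state.

    ``discarded``: the circuit is filled with the patient's blood and the
    priming saline is drained — in-body blood volume falls by the circuit
    volume, composition unchanged.  ``infused``: the saline is given to the
    patient while the circuit fills with blood — total circulating volume
    grows by the circuit volume and plasma is diluted by isotonic saline.
    In both cases the circulation volumes are redistributed quasi-statically
    (the loop equilibrates within seconds) with the access flows connected.
    """
    y = y_pre.copy()
    mode = model.protocol.priming
    v_circ = model.protocol.circuit_volume
    if mode == "none" or v_circ == 0.0:
        model.v_circ = 0.0
        return y
    blood0 = y[SL_BLOOD].sum()
    model.v_circ = v_circ
    f0 = model._fluxes(0.0, y_pre)
    q_l0 = f0["q_l"]
    q_b = model.protocol.blood_flow
    sources = np.zeros(N_COMP)
    sources[I_CAP] -= q_l0   # pre-dialysis filtration leaving the capillaries
    sources[I_LV] += q_l0
    sources[I_LA] -= q_b
    sources[I_SV] += q_b
    if mode == "discarded":
        y[SL_BLOOD] = _quasi_steady_volumes(model, blood0 - v_circ, sources)
    elif mode == "infused":
        # 220 mL blood to the circuit, 220 mL saline into the veins:
        # in-body volume unchanged, composition diluted
        y[SL_BLOOD] = _quasi_steady_volumes(model, blood0, sources)
        y[SL_NPL][SOLUTES.index("na")] += SALINE_NA * v_circ / 1000.0
        y[SL_NPL][SOLUTES.index("cl")] += SALINE_CL * v_circ / 1000.0
    return y


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Trajectory:
    """Densely sampled session trajectory with derived Starling series."""

    data: pd.DataFrame
    protocol: SessionProtocol
    model: Model
    solver_stats: dict

    @property
    def times(self) -> np.ndarray:
        return self.data["t"].to_numpy()

    def __getitem__(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy()


_DERIVED_DOC = {
    "v_plasma": "total circulating plasma volume incl. extracorporeal, mL",
    "rbv": "relative blood volume, % of the value at t=0",
}


def run_session(patient: VirtualPatient, protocol: SessionProtocol,
                sample: float = 0.5, rtol: float = 1e-8,
                model: Model | None = None) -> Trajectory:
    """Simulate one session and return the sampled trajectory.

    The forward model is deterministic; ``sample`` sets the fixed output
    grid (min) obtained from the solver's dense output.
    """
    m = model or build_model(patient, protocol)
    y0 = m.y0
    n = int(round(protocol.duration / sample))
    t_eval = np.linspace(0.0, protocol.duration, n + 1)
    atol = 1e-9 * np.maximum(np.abs(y0), 1.0)
    res = solve_ivp(m.rhs, (0.0, protocol.duration), y0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not res.success:
        t_fail = res.t[-1] if len(res.t) else 0.0
        raise RuntimeError(
            f"ODE solver failed at t={t_fail:.2f} min: {res.message}; "
            f"state snapshot: {res.y[:, -1] if res.y.size else y0}")

    rows = []
    for k, t in enumerate(res.t):
        y = res.y[:, k]
        f = m._fluxes(t, y)
        u = f["u"]
        rows.append(dict(
            t=t,
            v_plasma=u["v_plasma"],
            v_blood=u["total_blood"],
            v_is=u["v_is"], v_ic=u["v_ic"],
            hct=u["hct"], c_tp=u["c_tp"], c_tp_is=u["c_tp_is"],
            a_pl=f["a_pl"], a_is=f["a_is"],
            p_c=f["p_c"], p_is=f["p_is"], p_sv=f["pressures"][I_SV],
            p_la=f["pressures"][I_LA], p_rh=f["pressures"][I_RH],
            pi_pl_alb=f["pi_pl"][0], pi_pl_glob=f["pi_pl"][1],
            pi_pl=f["pi_pl"].sum(),
            pi_is_alb=f["pi_is"][0], pi_is_glob=f["pi_is"][1],
            pi_is=f["pi_is"].sum(),
            osm_term=float(m.alphas @ f["osm"]),
            j_v_large=f["j_v"][0], j_v_small=f["j_v"][1],
            j_v_ultrasmall=f["j_v"][2], j_v=f["j_v"].sum(),
            q_lymph=f["q_l"], uf=f["uf"], lps=f["kf"],
        ))
    df = pd.DataFrame(rows)
    df["rbv"] = df["v_blood"] / df["v_blood"].iloc[0] * 100.0
    stats = dict(nfev=int(res.nfev), njev=int(res.njev), nlu=int(res.nlu),
                 status=int(res.status))
    return Trajectory(data=df, protocol=protocol, model=m, solver_stats=stats)


# ---------------------------------------------------------------------------
# scenario battery
# ---------------------------------------------------------------------------

def scenario_protocols() -> dict[str, SessionProtocol]:
    """The named study scenarios (constant and ramped LpS, durations, UF,
    priming variants)."""
    basal = dict(duration=240.0, uf_total=3000.0)
    return {
        "basal": SessionProtocol(**basal, lps_start=6.0),
        "lps4": SessionProtocol(**basal, lps_start=4.0),
        "lps8": SessionProtocol(**basal, lps_start=8.0),
        "lps_ramp_down": SessionProtocol(**basal, lps_start=6.0, lps_end=4.0),
        "lps_ramp_up": SessionProtocol(**basal, lps_start=6.0, lps_end=8.0),
        "dur180": SessionProtocol(duration=180.0, uf_total=3000.0),
        "dur300": SessionProtocol(duration=300.0, uf_total=3000.0),
        "uf10": SessionProtocol(duration=240.0, uf_total=2400.0),
        "uf15": SessionProtocol(duration=240.0, uf_total=3600.0),
        "infused_basal": SessionProtocol(**basal, priming="infused"),
        "infused_lps4": SessionProtocol(**basal, priming="infused", lps_start=4.0),
        "infused_lps8": SessionProtocol(**basal, priming="infused", lps_start=8.0),
    }


def scenario_battery(patient: VirtualPatient,
                     names: list[str] | None = None) -> dict[str, Trajectory]:
    """Run the named scenario set and return trajectories keyed by scenario."""
    protocols = scenario_protocols()
    names = names or list(protocols)
    return {name: run_session(patient, protocols[name]) for name in names}


def solve_initial_steady_state(patient: VirtualPatient,
                               protocol: SessionProtocol | None = None
                               ) -> tuple[np.ndarray, float]:
    """Pre-priming steady state and the solved initial capillary pressure."""
    m = build_model(patient, protocol or SessionProtocol.flatline())
    return m.y_pre, m.pc0
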