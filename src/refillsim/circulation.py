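"""Nine-compartment closed-loop circulation with two continuous-flow pumps
and a four-mechanism baroreflex.

The loop is: large arteries -> small arteries/arterioles -> systemic
capillaries -> small veins/venules -> large veins -> right heart -> (pump) ->
pulmonary arteries -> pulmonary veins -> left heart -> (pump) -> large
arteries.  Blood is two-phase (plasma + erythrocytes) with a uniform
hematocrit assumption; the heart chambers are abstracted as continuous-flow
pumps whose outflow is linear in filling pressure, scaled by the
baroreflex-controlled heart-rate and contractility factors.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .params import COMPARTMENTS, VirtualPatient

N_COMP = len(COMPARTMENTS)
IDX = {name: i for i, name in enumerate(COMPARTMENTS)}

# passive links: (upstream, downstream); pumps sit at RH->PA and LH->LA
PASSIVE_LINKS = (
    ("large_arteries", "small_arteries"),
    ("small_arteries", "capillaries"),
    ("capillaries", "small_veins"),
    ("small_veins", "large_veins"),
    ("large_veins", "right_heart"),
    ("pulmonary_arteries", "pulmonary_veins"),
    ("pulmonary_veins", "left_heart"),
)


def compartment_pressures(volumes: np.ndarray, compliances: np.ndarray,
                          unstressed: np.ndarray) -> np.ndarray:
    """Elastance relation P = (V - V_u) / C, per compartment (mmHg)."""
    if np.any(np.asarray(compliances) <= 0):
        raise ValueError("compliances must be > 0")
    return (np.asarray(volumes, float) - np.asarray(unstressed, float)) / compliances


def pump_flow(filling_pressure: float, gain: float, scaling: float = 1.0) -> float:
    """Continuous-flow pump law: linear in filling pressure, no backflow."""
    return gain * scaling * max(filling_pressure, 0.0)


def vascular_flows(pressures: np.ndarray, resistances: np.ndarray,
                   pump_gains: tuple[float, float],
                   pump_scaling: float = 1.0,
                   resistance_scaling: float = 1.0) -> np.ndarray:
    """Per-link flows (mL/min) around the loop, in compartment order.

    Returns a length-9 array where entry k is the outflow of compartment k.
    ``resistance_scaling`` multiplies the arteriolar (small-artery) outflow
    resistance; ``pump_scaling`` multiplies both pump gains.
    """
    p = np.asarray(pressures, float)
    r = np.asarray(resistances, float)
    if np.any(r <= 0):
        raise ValueError("resistances must be > 0")
    q = np.empty(N_COMP)
    scale = {"small_arteries": resistance_scaling}
    for k, (up, dn) in enumerate(PASSIVE_LINKS):
        i, j = IDX[up], IDX[dn]
        q[i] = (p[i] - p[j]) / (r[k] * scale.get(up, 1.0))
    q[IDX["right_heart"]] = pump_flow(p[IDX["right_heart"]], pump_gains[0],
                                      pump_scaling)
    q[IDX["left_heart"]] = pump_flow(p[IDX["left_heart"]], pump_gains[1],
                                     pump_scaling)
    return q


# ---------------------------------------------------------------------------
# baroreflex
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BaroreflexParams:
    """Gains, saturation amplitudes and time constants of the four arms."""

    set_point_arterial: float
    set_point_cardiopulmonary: float
    gain_hr: float
    gain_contractility: float
    gain_resistance_hp: float
    gain_resistance_lp: float
    gain_vu_hp: float
    gain_vu_lp: float
    amp_hr: float
    amp_contractility: float
    amp_resistance: float
    amp_vu: float
    tau_hr: float
    tau_contractility: float
    tau_resistance: float
    tau_vu: float

    @classmethod
    def from_patient(cls, patient: VirtualPatient,
                     set_point_arterial: float,
                     set_point_cardiopulmonary: float) -> "BaroreflexParams":
        r = patient.registry
        return cls(
            set_point_arterial=set_point_arterial,
            set_point_cardiopulmonary=set_point_cardiopulmonary,
            gain_hr=r["baro_gain_hr"],
            gain_contractility=r["baro_gain_contractility"],
            gain_resistance_hp=r["baro_gain_resistance_hp"],
            gain_resistance_lp=r["baro_gain_resistance_lp"],
            gain_vu_hp=r["baro_gain_vu_hp"],
            gain_vu_lp=r["baro_gain_vu_lp"],
            amp_hr=r["baro_amp_hr"],
            amp_contractility=r["baro_amp_contractility"],
            amp_resistance=r["baro_amp_resistance"],
            amp_vu=r["baro_amp_vu"],
            tau_hr=r["baro_tau_hr"],
            tau_contractility=r["baro_tau_contractility"],
            tau_resistance=r["baro_tau_resistance"],
            tau_vu=r["baro_tau_vu"],
        )


def _sigmoid(drive: float, amplitude: float) -> float:
    if amplitude == 0.0:
        return 0.0
    return amplitude * np.tanh(drive / amplitude)


def baroreflex_static_targets(params: BaroreflexParams,
                              p_arterial: float,
                              p_cardiopulmonary: float) -> np.ndarray:
    """Static characteristics of the four controller outputs.

    Order: heart-rate scaling, contractility scaling, arteriolar resistance
    scaling (all neutral at 1) and venous unstressed-volume offset in mL
    (neutral at 0).  Errors are set point minus afferent, so a pressure fall
    drives tachycardia, vasoconstriction and venoconstriction.
    """
    e_h = params.set_point_arterial - p_arterial
    e_l = params.set_point_cardiopulmonary - p_cardiopulmonary
    return np.array([
        1.0 + _sigmoid(params.gain_hr * e_h, params.amp_hr),
        1.0 + _sigmoid(params.gain_contractility * e_h, params.amp_contractility),
        1.0 + _sigmoid(params.gain_resistance_hp * e_h
                       + params.gain_resistance_lp * e_l, params.amp_resistance),
        -_sigmoid(params.gain_vu_hp * e_h + params.gain_vu_lp * e_l,
                  params.amp_vu),
    ])


def baroreflex_update(state: np.ndarray, params: BaroreflexParams,
                      p_arterial: float, p_cardiopulmonary: float,
                      dt: float) -> np.ndarray:
    """First-order Euler relaxation of controller outputs over ``dt`` minutes."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    target = baroreflex_static_targets(params, p_arterial, p_cardiopulmonary)
    taus = np.array([params.tau_hr, params.tau_contractility,
                     params.tau_resistance, params.tau_vu])
    return state + (target - state) * (1.0 - np.exp(-dt / taus))


def baroreflex_derivative(state: np.ndarray, params: BaroreflexParams,
                          p_arterial: float,
                          p_cardiopulmonary: float) -> np.ndarray:
    """d(state)/dt of the four controllers (used inside the ODE system)."""
    target = baroreflex_static_targets(params, p_arterial, p_cardiopulmonary)
    taus = np.array([params.tau_hr, params.tau_contractility,
                     params.tau_resistance, params.tau_vu])
    return (target - state) / taus
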