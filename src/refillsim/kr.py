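"""Vascular-refilling analysis: refilling rate, Kr(t), Starling-force
decomposition, lymph expressed in pressure units, and the local relative
sensitivity screen.

The refilling coefficient is

    Kr(t) = R(t) / (pi_pl(t) - pi_pl(0)),    R(t) = dV_p/dt + UF(t)

with V_p the total circulating plasma volume and pi_pl the total plasma
oncotic pressure from the albumin/globulin polynomials.  Kr diverges as
t -> 0 (infinitesimal denominator), so curves are reported from minute 5
onward and points with |pi_pl(t) - pi_pl(0)| below a tolerance are masked.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .dialysis import SessionProtocol
from .params import ParameterRegistry, VirtualPatient
from .simulator import Trajectory, build_model, run_session

#: points with a plasma oncotic change smaller than this are masked (mmHg)
DENOMINATOR_TOL = 0.05

__all__ = [
    "KrCurve", "StarlingDecomposition", "SensitivityResult",
    "refilling_rate", "kr_curve", "kr_value_at", "starling_decomposition",
    "relative_sensitivity", "relative_sensitivity_from_values",
    "sensitivity_screen",
]


@dataclasses.dataclass
class KrCurve:
    """Kr(t) together with its cached inputs."""

    times: np.ndarray          # min
    kr: np.ndarray             # mL/min/mmHg, NaN where masked
    refilling_rate: np.ndarray  # mL/min
    uf: np.ndarray             # mL/min
    dvp_dt: np.ndarray         # mL/min
    delta_pi_pl: np.ndarray    # mmHg

    def at(self, t: float) -> float:
        """Kr interpolated at time ``t`` (min)."""
        return float(np.interp(t, self.times, self.kr))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(t=self.times, kr=self.kr,
                                 refilling_rate=self.refilling_rate,
                                 uf=self.uf, dvp_dt=self.dvp_dt,
                                 delta_pi_pl=self.delta_pi_pl))


def refilling_rate(traj: Trajectory, from_fluxes: bool = False) -> np.ndarray:
    """Vascular refilling rate R(t) in mL/min.

    Default route: R = dV_p/dt + UF with the plasma-volume derivative from
    second-order central differences on the fixed output grid.  With
    ``from_fluxes`` the same quantity is computed independently from the
    transcapillary fluxes and lymph flow, R = -sum_i J_v,i + Q_L; the two
    must agree and serve as a cross-check of the volume bookkeeping.
    """
    if from_fluxes:
        return -traj["j_v"] + traj["q_lymph"]
    dvp = np.gradient(traj["v_plasma"], traj.times, edge_order=2)
    return dvp + traj["uf"]


def kr_curve(traj: Trajectory, start: float = 5.0,
             tol: float = DENOMINATOR_TOL) -> KrCurve:
    """Kr(t) on [start, session end] with near-zero denominators masked."""
    t = traj.times
    dvp = np.gradient(traj["v_plasma"], t, edge_order=2)
    uf = traj["uf"]
    r = dvp + uf
    dpi = traj["pi_pl"] - traj["pi_pl"][0]
    mask = (t >= start) & (np.abs(dpi) >= tol)
    kr = np.full_like(r, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        kr[mask] = r[mask] / dpi[mask]
    sel = t >= start
    if not np.any(np.isfinite(kr[sel])):
        raise ValueError("Kr curve entirely masked: plasma oncotic pressure "
                         "never departs from its initial value")
    return KrCurve(times=t[sel], kr=kr[sel], refilling_rate=r[sel],
                   uf=uf[sel], dvp_dt=dvp[sel], delta_pi_pl=dpi[sel])


def kr_value_at(patient: VirtualPatient, protocol: SessionProtocol,
                t_eval: float) -> float:
    """End-to-end convenience: simulate a session and read Kr at ``t_eval``."""
    traj = run_session(patient, protocol)
    return kr_curve(traj).at(t_eval)


# ---------------------------------------------------------------------------
# Starling decomposition
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StarlingDecomposition:
    """Per-force changes versus t=0, signed so that positive favors
    transcapillary absorption (a falling capillary pressure plots as a
    rising curve, a rising interstitial oncotic pressure as a falling one).
    The lymph-equivalent term Q_L/LpS is reported separately from the net
    driving pressure."""

    times: np.ndarray
    capillary_pressure: np.ndarray
    interstitial_pressure: np.ndarray
    plasma_oncotic: np.ndarray
    interstitial_oncotic: np.ndarray
    small_solute_osmotic: np.ndarray
    lymph_equivalent: np.ndarray     # delta of Q_L / LpS, mmHg
    net: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(
            t=self.times,
            capillary_pressure=self.capillary_pressure,
            interstitial_pressure=self.interstitial_pressure,
            plasma_oncotic=self.plasma_oncotic,
            interstitial_oncotic=self.interstitial_oncotic,
            small_solute_osmotic=self.small_solute_osmotic,
            lymph_equivalent=self.lymph_equivalent,
            net=self.net,
        ))


def starling_decomposition(traj: Trajectory) -> StarlingDecomposition:
    """Intradialytic change of each Starling force, absorption-positive."""
    def delta(col):
        x = traj[col]
        return x - x[0]

    cap = -delta("p_c")                    # falling P_c favors absorption
    inter = delta("p_is")                  # falling P_is favors filtration
    pi_pl = delta("pi_pl")                 # rising pi_pl favors absorption
    pi_is = -delta("pi_is")
    osm = delta("osm_term")                # conductivity-weighted, plasma-side
    lymph_eq = (traj["q_lymph"] - traj["q_lymph"][0]) / traj["lps"]
    net = cap + inter + pi_pl + pi_is + osm
    return StarlingDecomposition(
        times=traj.times, capillary_pressure=cap, interstitial_pressure=inter,
        plasma_oncotic=pi_pl, interstitial_oncotic=pi_is,
        small_solute_osmotic=osm, lymph_equivalent=lymph_eq, net=net)


# ---------------------------------------------------------------------------
# local relative sensitivity
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    baseline: float
    t_eval: float            # min
    sensitivity: float       # dimensionless log-derivative


def relative_sensitivity_from_values(kr_plus: float, kr_minus: float,
                                     theta: float, delta: float,
                                     kr_ref: float) -> float:
    """Central-difference relative sensitivity S = dKr/dtheta * theta/Kr."""
    if theta == 0.0 or kr_ref == 0.0:
        raise ValueError("relative sensitivity undefined for zero parameter "
                         "or zero Kr")
    return (kr_plus - kr_minus) / (2.0 * delta) * theta / kr_ref


def relative_sensitivity(registry: ParameterRegistry, protocol: SessionProtocol,
                         parameter: str, t_eval: float,
                         rel_step: float = 1e-4) -> SensitivityResult:
    """Relative sensitivity of Kr(t_eval) to one registry parameter.

    Two full re-simulations with the parameter moved by +/-0.01 % (each
    re-solving the pre-dialysis steady state) around its baseline; Kr is
    read at ``t_eval`` from each run.
    """
    theta = registry[parameter]
    values = {}
    for sign in (+1.0, -1.0):
        reg = registry.perturbed(parameter, 1.0 + sign * rel_step)
        pat = VirtualPatient(reg)
        proto = protocol
        if parameter == "lps" and (protocol.lps_start is not None
                                   or protocol.lps_end is not None):
            # an explicit protocol LpS profile must carry the perturbation
            scale = 1.0 + sign * rel_step
            proto = dataclasses.replace(
                protocol,
                lps_start=None if protocol.lps_start is None
                else protocol.lps_start * scale,
                lps_end=None if protocol.lps_end is None
                else protocol.lps_end * scale)
        values[sign] = kr_value_at(pat, proto, t_eval)
    kr_ref = 0.5 * (values[+1.0] + values[-1.0])
    if not np.isfinite(kr_ref) or kr_ref == 0.0:
        raise ValueError(f"Kr({t_eval} min) is not finite/non-zero; cannot "
                         f"compute sensitivity to {parameter}")
    s = relative_sensitivity_from_values(values[+1.0], values[-1.0], theta,
                                         rel_step * theta, kr_ref)
    return SensitivityResult(parameter=parameter, baseline=theta,
                             t_eval=t_eval, sensitivity=s)


def sensitivity_screen(registry: ParameterRegistry, protocol: SessionProtocol,
                       t_eval: float, parameters: list[str] | None = None,
                       threshold: float = 0.5) -> pd.DataFrame:
    """Screen Kr(t_eval) sensitivity over the parameter registry.

    Returns the full table sorted by |S| (descending) with a boolean
    ``above_threshold`` column flagging |S| > ``threshold``.  Two
    re-simulations per parameter; restrict ``parameters`` to subsets for
    quick looks.
    """
    keys = parameters or registry.sensitivity_keys()
    rows = []
    for key in keys:
        try:
            res = relative_sensitivity(registry, protocol, key, t_eval)
        except (ValueError, RuntimeError):
            continue
        rows.append(dict(parameter=key, baseline=res.baseline,
                         t_eval=t_eval, sensitivity=res.sensitivity))
    df = pd.DataFrame(rows)
    df["abs_sensitivity"] = df["sensitivity"].abs()
    df = df.sort_values("abs_sensitivity", ascending=False,
                        ignore_index=True)
    df["above_threshold"] = df["abs_sensitivity"] > threshold
    return df
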