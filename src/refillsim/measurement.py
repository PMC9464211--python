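"""Measurement emulation: clinical-style series from simulated truth, and
the hematocrit-based Kr estimator as it would run on real data.

Clinically, relative blood volume is tracked from hematocrit under the
assumption that total erythrocyte volume stays constant, so

    V_p(t) / V_p(0) = [Hct(0) (1 - Hct(t))] / [Hct(t) (1 - Hct(0))].

An exponential-plus-offset curve is fitted to the estimated plasma volume
and its analytic derivative feeds Kr(t) together with the total-protein
channel, whose oncotic pressure comes from the Landis-Pappenheimer
polynomial (the estimator never sees the simulator's protein fractions).
This closes the loop between model truth and what a bedside estimator
would report.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .kr import DENOMINATOR_TOL, KrCurve
from .microvascular import pi_total_landis_pappenheimer
from .simulator import Trajectory

__all__ = ["MeasurementSeries", "synthesize_measurements",
           "plasma_volume_from_rbv", "PlasmaVolumeFit", "kr_from_measurements"]


@dataclasses.dataclass
class MeasurementSeries:
    """Synthetic bedside monitoring series with multiplicative Gaussian noise."""

    times_hct: np.ndarray        # min
    hematocrit: np.ndarray       # fraction
    times_protein: np.ndarray    # min
    total_protein: np.ndarray    # g/dL
    noise_cv_hct: float
    noise_cv_protein: float
    seed: int | None

    @property
    def rbv(self) -> np.ndarray:
        """Relative blood volume (%), RBV(0) = 100, constant-RBC assumption."""
        h0 = self.hematocrit[0]
        return h0 / self.hematocrit * 100.0

    def to_frame(self) -> pd.DataFrame:
        hct = pd.DataFrame(dict(t=self.times_hct, channel="hematocrit",
                                value=self.hematocrit))
        tp = pd.DataFrame(dict(t=self.times_protein, channel="total_protein",
                               value=self.total_protein))
        return pd.concat([hct, tp], ignore_index=True)


def synthesize_measurements(traj: Trajectory,
                            hct_interval: float = 10.0,
                            protein_interval: float = 30.0,
                            noise_cv_hct: float = 0.01,
                            noise_cv_protein: float = 0.02,
                            seed: int | None = None) -> MeasurementSeries:
    """Sample hematocrit and total-protein readings from a trajectory.

    Hematocrit is the simulated RBC fraction of circulating blood; both
    channels get multiplicative Gaussian noise with the given coefficients
    of variation.  Reproducible under a fixed seed.
    """
    t_end = traj.times[-1]
    t_hct = np.arange(0.0, t_end + 1e-9, hct_interval)
    t_tp = np.arange(0.0, t_end + 1e-9, protein_interval)
    if t_hct[-1] > traj.times[-1] or t_hct[0] < traj.times[0]:
        raise ValueError("sampling schedule outside trajectory")
    rng = np.random.default_rng(seed)
    hct = np.interp(t_hct, traj.times, traj["hct"])
    tp = np.interp(t_tp, traj.times, traj["c_tp"])
    hct = hct * (1.0 + noise_cv_hct * rng.standard_normal(hct.size))
    tp = tp * (1.0 + noise_cv_protein * rng.standard_normal(tp.size))
    if np.any((hct <= 0.1) | (hct >= 0.6)):
        raise ValueError("synthesized hematocrit outside the plausible "
                         "(0.1, 0.6) range; reduce noise")
    return MeasurementSeries(times_hct=t_hct, hematocrit=hct,
                             times_protein=t_tp, total_protein=tp,
                             noise_cv_hct=noise_cv_hct,
                             noise_cv_protein=noise_cv_protein, seed=seed)


@dataclasses.dataclass
class PlasmaVolumeFit:
    """Exponential-plus-offset fit V_p(t) = a + b exp(-t/tau)."""

    a: float
    b: float
    tau: float
    times: np.ndarray
    v_p: np.ndarray          # ratio-based estimates at sample times (mL)

    def value(self, t):
        return self.a + self.b * np.exp(-np.asarray(t, float) / self.tau)

    def derivative(self, t):
        """Analytic dV_p/dt in mL/min."""
        return -self.b / self.tau * np.exp(-np.asarray(t, float) / self.tau)


def plasma_volume_from_rbv(series: MeasurementSeries,
                           v_p0: float) -> PlasmaVolumeFit:
    """Plasma volume series from hematocrit plus an exponential fit.

    ``v_p0`` is the (assumed known) pre-dialysis plasma volume in mL.  The
    constant-RBC ratio converts hematocrit to V_p(t)/V_p(0); a least-squares
    exponential-plus-offset fit provides the smooth instantaneous rate.
    """
    if series.times_hct.size < 4:
        raise ValueError("need at least 4 hematocrit samples to fit")
    h = series.hematocrit
    h0 = h[0]
    ratio = (h0 * (1.0 - h)) / (h * (1.0 - h0))
    v_p = ratio * v_p0
    t = series.times_hct
    span = max(t[-1], 1.0)

    def model(tt, a, b, log_tau):
        return a + b * np.exp(-tt / np.exp(log_tau))

    drop = v_p[0] - v_p[-1]
    p0 = (v_p[-1] - 0.5 * abs(drop), v_p[0] - v_p[-1] + 0.5 * abs(drop),
          np.log(span / 2.0))
    try:
        popt, _ = curve_fit(model, t, v_p, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"plasma-volume exponential fit failed: {exc}")
    a, b, log_tau = popt
    return PlasmaVolumeFit(a=float(a), b=float(b), tau=float(np.exp(log_tau)),
                           times=t, v_p=v_p)


def kr_from_measurements(series: MeasurementSeries, uf_rate: float,
                         v_p0: float, start: float = 5.0,
                         tol: float = DENOMINATOR_TOL) -> KrCurve:
    """Clinical-style Kr from measurement series alone.

    Kr(t) = (dV_p/dt + UF) / (pi_LP(C(t)) - pi_LP(C(0))) with the plasma
    oncotic pressure from total protein via Landis-Pappenheimer and dV_p/dt
    from the exponential fit; reported from minute 5, masked where the
    oncotic change is below tolerance.
    """
    fit = plasma_volume_from_rbv(series, v_p0)
    t = series.times_protein
    pi = pi_total_landis_pappenheimer(series.total_protein)
    dpi = pi - pi[0]
    dvp = fit.derivative(t)
    r = dvp + uf_rate
    kr = np.full_like(r, np.nan)
    mask = (t >= start) & (np.abs(dpi) >= tol)
    with np.errstate(divide="ignore", invalid="ignore"):
        kr[mask] = r[mask] / dpi[mask]
    sel = t >= start
    if not np.any(np.isfinite(kr[sel])):
        raise ValueError("estimated Kr curve entirely masked")
    return KrCurve(times=t[sel], kr=kr[sel], refilling_rate=r[sel],
                   uf=np.full(sel.sum(), uf_rate), dvp_dt=dvp[sel],
                   delta_pi_pl=dpi[sel])
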