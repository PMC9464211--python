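"""Dialyzer solute exchange, ultrafiltration profiles and priming.

A session is described by a :class:`SessionProtocol`: duration, total net
ultrafiltration (delivered at a constant rate), the priming mode for the
220 mL extracorporeal circuit (saline discarded, or infused to the patient),
dialyzer blood flow, per-solute clearances/dialysances relative to the urea
clearance, and a constant-or-linear profile for the whole-body capillary
hydraulic conductivity LpS over the session.
"""

from __future__ import annotations

import dataclasses

from .params import SOLUTES, ParameterRegistry

PRIMING_MODES = ("discarded", "infused", "none")

#: 0.9 % saline used for infused priming, mmol/L.
SALINE_NA = 154.0
SALINE_CL = 154.0


@dataclasses.dataclass(frozen=True)
class SessionProtocol:
    """Hemodialysis scenario definition (durations in min, volumes in mL)."""

    duration: float = 240.0
    uf_total: float = 3000.0
    priming: str = "discarded"
    circuit_volume: float = 220.0   # 100 mL dialyzer + 120 mL tubing
    blood_flow: float = 300.0       # mL/min through the extracorporeal circuit
    urea_clearance: float = 200.0   # mL/min; other solutes scale from this
    lps_start: float | None = None  # mL/min/mmHg; None -> registry value
    lps_end: float | None = None    # None -> constant at lps_start

    def __post_init__(self) -> None:
        if self.priming not in PRIMING_MODES:
            raise ValueError(f"priming must be one of {PRIMING_MODES}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        for lps in (self.lps_start, self.lps_end):
            if lps is not None and lps <= 0:
                raise ValueError("LpS profile must be strictly positive")
        if self.uf_total < 0:
            raise ValueError("total ultrafiltration must be >= 0")

    @classmethod
    def flatline(cls, duration: float = 300.0) -> "SessionProtocol":
        """No-intervention protocol: no circuit, no UF, no dialysis."""
        return cls(duration=duration, uf_total=0.0, priming="none",
                   circuit_volume=0.0, blood_flow=0.0, urea_clearance=0.0)

    # -- ultrafiltration ----------------------------------------------------
    @property
    def uf_rate(self) -> float:
        """Constant ultrafiltration rate, mL/min (priming-corrected).

        With the priming saline infused, the circuit volume is added to the
        delivered ultrafiltration so the same *net* fluid removal is reached.
        """
        total = self.uf_total
        if self.priming == "infused":
            total += self.circuit_volume
        return total / self.duration

    def ultrafiltration_profile(self, t: float) -> float:
        """UF(t) in mL/min; raises outside the session."""
        if t < 0 or t > self.duration:
            raise ValueError(f"t={t} outside session [0, {self.duration}] min")
        return self.uf_rate

    # -- LpS profile ---------------------------------------------------------
    def lps_profile(self, t: float, default: float = 6.0) -> float:
        """LpS(t) in mL/min/mmHg (linear ramp over the session if configured).

        ``default`` supplies the whole-body conductivity when the protocol
        does not override it (normally the patient registry's ``lps``).
        """
        start = self.lps_start if self.lps_start is not None else default
        if self.lps_end is None:
            return start
        frac = min(max(t / self.duration, 0.0), 1.0)
        return start + (self.lps_end - start) * frac

    # -- per-solute dialyzer settings ----------------------------------------
    def clearances(self, registry: ParameterRegistry) -> dict[str, float]:
        return {s: self.urea_clearance * registry[f"{s}_clearance_scale"]
                for s in SOLUTES}


def dialyzer_solute_exchange(clearance: float, c_plasma_water: float,
                             c_dialysate: float, alpha_d: float = 1.0) -> float:
    """Solute removal rate in the dialyzer, mmol/min.

    ``removal = clearance * (alpha_d * c_pl,water - c_dialysate)``; negative
    values mean net uptake from the dialysis fluid (e.g. bicarbonate).
    ``alpha_d`` is the Gibbs-Donnan coefficient across the dialyzer membrane.
    """
    if clearance < 0:
        raise ValueError("clearance must be >= 0")
    return clearance * (alpha_d * c_plasma_water - c_dialysate) / 1000.0
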