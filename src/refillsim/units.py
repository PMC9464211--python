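"""Centralized unit harmonization.

All internal computation uses mL, min, mmHg, mmol and g.  Literature values
quoted in other units (L/day, mL/mmHg/h, g/dL, L) are converted exactly once,
through the factors below, when a :class:`~refillsim.params.VirtualPatient`
is built from the registry.
"""

#: mmHg per (mmol/L) at body temperature (van't Hoff RT).
RT_MMHG_PER_MMOL_L = 19.3

L_PER_DAY_TO_ML_PER_MIN = 1000.0 / (24.0 * 60.0)
ML_PER_MMHG_H_TO_ML_PER_MMHG_MIN = 1.0 / 60.0
L_TO_ML = 1000.0
G_DL_TO_G_ML = 0.01


def l_per_day(value: float) -> float:
    """L/day -> mL/min."""
    return value * L_PER_DAY_TO_ML_PER_MIN


def ml_per_mmhg_h(value: float) -> float:
    """mL/mmHg/h -> mL/mmHg/min."""
    return value * ML_PER_MMHG_H_TO_ML_PER_MMHG_MIN


def g_per_dl(value: float) -> float:
    """g/dL -> g/mL."""
    return value * G_DL_TO_G_ML
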