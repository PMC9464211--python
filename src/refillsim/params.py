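"""Virtual-patient parameter registry.

The model is driven by a flat ``key -> value`` registry.  Every entry carries
units and a provenance tag: ``"literature"`` for values taken directly from
published sources, ``"default"`` for package-defined reference values (chosen
once to yield textbook physiology and documented in ``docs/methods.md``).

The registry is the single enumerable parameter space used by the local
sensitivity screen, so every numeric entry here can be perturbed and the
whole pipeline (steady-state initialization + session simulation + Kr
analysis) re-run.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Mapping

import numpy as np

from . import units

COMPARTMENTS = (
    "large_arteries",
    "small_arteries",
    "capillaries",
    "small_veins",
    "large_veins",
    "right_heart",
    "pulmonary_arteries",
    "pulmonary_veins",
    "left_heart",
)

#: Small solutes tracked in every fluid space.  ``other_anions`` is the
#: collective electroneutrality carrier (average charge -2).
SOLUTES = ("na", "k", "cl", "hco3", "urea", "creatinine", "other_anions")

PORES = ("large", "small", "ultrasmall")


@dataclasses.dataclass(frozen=True)
class ParamDef:
    default: float
    units: str
    provenance: str  # "literature" | "default"
    description: str = ""


def _circulation_defs() -> dict[str, ParamDef]:
    # fraction of total blood volume, compliance (mL/mmHg), normal pressure (mmHg)
    frac = dict(
        large_arteries=0.09, small_arteries=0.07, capillaries=0.06,
        small_veins=0.39, large_veins=0.18, right_heart=0.03,
        pulmonary_arteries=0.03, pulmonary_veins=0.12, left_heart=0.03,
    )
    compl = dict(
        large_arteries=1.2, small_arteries=0.8, capillaries=2.0,
        small_veins=90.0, large_veins=45.0, right_heart=8.0,
        pulmonary_arteries=3.5, pulmonary_veins=15.0, left_heart=8.0,
    )
    pres = dict(
        large_arteries=93.0, small_arteries=60.0, capillaries=17.0,
        small_veins=12.0, large_veins=4.0, right_heart=3.0,
        pulmonary_arteries=15.0, pulmonary_veins=8.0, left_heart=7.0,
    )
    out: dict[str, ParamDef] = {}
    for c in COMPARTMENTS:
        out[f"frac_{c}"] = ParamDef(frac[c], "-", "default",
                                    f"fraction of total blood volume in {c}")
        out[f"compliance_{c}"] = ParamDef(compl[c], "mL/mmHg", "default",
                                          f"vascular compliance of {c}")
        out[f"pressure_{c}"] = ParamDef(pres[c], "mmHg", "default",
                                        f"normal (pre-dialysis) pressure of {c}")
    return out


def _solute_defs() -> dict[str, ParamDef]:
    # plasma conc (mmol/L plasma), intracellular conc (mmol/L water),
    # dialysate conc (mmol/L), Stokes radius (Angstrom), valence, osmotic
    # coefficient, capillary PS (mL/min), cell-membrane PS (mL/min),
    # cell-membrane reflection coefficient, clearance scale (x urea clearance),
    # dialyzer Gibbs-Donnan coefficient.
    tab = {
        #        cpl    cic    cdi    r    z    phi  psc    pscell sigc  clr  aD
        "na":   (138.0, 12.0, 140.0, 1.8,  1, 0.93, 1000.0,   0.0, 1.0, 1.0, 0.95),
        "k":    (  5.0, 140.0,  2.0, 1.6,  1, 0.93, 1000.0,   0.0, 1.0, 1.0, 0.95),
        "cl":   (102.0,   4.0, 111.0, 1.8, -1, 0.93, 1000.0,  0.0, 1.0, 1.0, 1.05),
        "hco3": ( 22.0,  10.0, 32.0, 2.0, -1, 0.93, 1000.0,  40.0, 0.6, 0.5, 1.05),
        "urea": ( 20.0,   0.0,  0.0, 2.6,  0, 1.00, 2500.0, 800.0, 0.05, 1.0, 1.0),
        "creatinine": (0.1, 0.0, 0.0, 3.0, 0, 1.00, 400.0, 100.0, 0.3, 0.9, 1.0),
        "other_anions": (2.5, 0.0, 0.0, 2.3, -2, 0.93, 100.0, 0.0, 1.0, 0.0, 1.0),
    }
    lit_conc = {"na", "k", "cl", "hco3", "urea"}  # pre-dialysis plasma levels
    out: dict[str, ParamDef] = {}
    for s, (cpl, cic, cdi, r, z, phi, psc, pscell, sigc, clr, ad) in tab.items():
        prov = "literature" if s in lit_conc else "default"
        out[f"{s}_plasma"] = ParamDef(cpl, "mmol/L plasma", prov,
                                      f"pre-dialysis plasma {s} concentration")
        out[f"{s}_intracellular"] = ParamDef(cic, "mmol/L water", "default",
                                             f"intracellular {s} concentration")
        out[f"{s}_dialysate"] = ParamDef(cdi, "mmol/L", "default",
                                         f"dialysate {s} concentration")
        out[f"{s}_radius"] = ParamDef(r, "Angstrom", "default",
                                      f"effective Stokes radius of {s}")
        out[f"{s}_valence"] = ParamDef(float(z), "-", "literature" if s ==
                                       "other_anions" else "default",
                                       f"ionic valence of {s}")
        out[f"{s}_phi"] = ParamDef(phi, "-", "default",
                                   f"osmotic activity coefficient of {s}")
        out[f"{s}_ps_capillary"] = ParamDef(psc, "mL/min", "default",
                                            f"whole-body capillary diffusive PS for {s}")
        out[f"{s}_ps_cell"] = ParamDef(pscell, "mL/min", "default",
                                       f"cell-membrane mass transfer coefficient for {s}")
        out[f"{s}_sigma_cell"] = ParamDef(sigc, "-", "default",
                                          f"cell-membrane osmotic reflection coefficient for {s}")
        out[f"{s}_clearance_scale"] = ParamDef(clr, "x urea clearance", "default",
                                               f"dialyzer clearance of {s} relative to urea")
        out[f"{s}_alpha_dialyzer"] = ParamDef(ad, "-", "default",
                                              f"Gibbs-Donnan coefficient of {s} across the dialyzer membrane")
    return out


PARAMETER_DEFS: dict[str, ParamDef] = {
    # --- body fluid spaces -------------------------------------------------
    "plasma_volume_normal": ParamDef(3.0, "L", "default",
                                     "normal plasma volume, 70-kg reference"),
    "hematocrit_normal": ParamDef(0.40, "-", "default", "normal hematocrit"),
    "v_is_normal": ParamDef(15.0, "L", "literature",
                            "normal interstitial fluid volume"),
    "v_ic_normal": ParamDef(23.0, "L", "default",
                            "normal intracellular water volume"),
    "fluid_overload": ParamDef(3.0, "L", "literature",
                               "pre-dialysis fluid overload, split proportionally"),
    # --- interstitium & lymph ---------------------------------------------
    "p_is_normal": ParamDef(-1.0, "mmHg", "literature",
                            "normal interstitial hydrostatic pressure"),
    "c_is_compliance_frac": ParamDef(0.12, "1/mmHg", "literature",
                                     "interstitial compliance as fraction of normal volume per mmHg"),
    "q_lymph_normal": ParamDef(8.0, "L/day", "literature",
                               "normal afferent lymph flow"),
    "lymph_sensitivity": ParamDef(43.1, "mL/mmHg/h", "literature",
                                  "lymph flow sensitivity to interstitial pressure"),
    "v_is_excluded_frac": ParamDef(0.5, "-", "literature",
                                   "volume excluded to proteins as fraction of normal interstitial volume"),
    # --- capillary wall (three-pore) ---------------------------------------
    "lps": ParamDef(6.0, "mL/min/mmHg", "literature",
                    "whole-body capillary hydraulic conductivity (K_f), basal"),
    "alpha_large": ParamDef(0.05, "-", "literature",
                            "fraction of LpS in large pores"),
    "alpha_small": ParamDef(0.85, "-", "literature",
                            "fraction of LpS in small pores"),
    "alpha_ultrasmall": ParamDef(0.10, "-", "literature",
                                 "fraction of LpS in ultrasmall pores (aquaporins)"),
    "r_pore_large": ParamDef(250.0, "Angstrom", "literature", "large pore radius"),
    "r_pore_small": ParamDef(45.0, "Angstrom", "literature", "small pore radius"),
    "r_pore_ultrasmall": ParamDef(2.0, "Angstrom", "literature",
                                  "ultrasmall pore radius"),
    "w_venous": ParamDef(0.8, "-", "literature",
                         "fraction of venous pressure change transmitted to capillaries"),
    # --- plasma proteins ---------------------------------------------------
    "total_protein_plasma": ParamDef(7.0, "g/dL", "default",
                                     "pre-dialysis total plasma protein"),
    "albumin_fraction_plasma": ParamDef(0.6, "-", "literature",
                                        "albumin mass fraction of plasma protein (A/G ratio 1.5)"),
    "albumin_fraction_is": ParamDef(0.6, "-", "default",
                                    "interstitial albumin fraction (initial guess; steady state refines)"),
    "r_albumin": ParamDef(35.5, "Angstrom", "literature", "albumin Stokes radius"),
    "r_globulin": ParamDef(52.0, "Angstrom", "literature", "globulin Stokes radius"),
    "mw_albumin": ParamDef(66.5, "kg/mol", "literature", "albumin molar mass"),
    "mw_globulin": ParamDef(160.0, "kg/mol", "default",
                            "representative globulin molar mass"),
    "z_albumin": ParamDef(-17.0, "-", "literature",
                          "albumin net charge at pH 7.4"),
    "z_globulin": ParamDef(-5.0, "-", "default", "mean globulin net charge"),
    "ps_albumin_large": ParamDef(4.8, "mL/min", "default",
                                 "diffusive PS of albumin, large pores"),
    "ps_albumin_small": ParamDef(0.04, "mL/min", "default",
                                 "diffusive PS of albumin, small pores"),
    "ps_globulin_large": ParamDef(3.12, "mL/min", "default",
                                  "diffusive PS of globulins, large pores"),
    "ps_globulin_small": ParamDef(0.01, "mL/min", "default",
                                  "diffusive PS of globulins, small pores"),
    "f_plasma_water_normal": ParamDef(0.93, "-", "literature",
                                      "normal plasma water fraction"),
    # --- cell membrane water -----------------------------------------------
    "lp_cell": ParamDef(0.05, "mL/min/mmHg", "default",
                        "whole-body cell membrane hydraulic conductance (osmotic relaxation over tens of minutes)"),
    # --- circulation -------------------------------------------------------
    "cardiac_output_normal": ParamDef(6.5, "L/min", "default",
                                      "normal cardiac output"),
    "p_sv_reference": ParamDef(12.0, "mmHg", "literature",
                               "initial small-vein pressure (venous coupling reference)"),
    # --- baroreflex --------------------------------------------------------
    "baro_gain_hr": ParamDef(0.02, "1/mmHg", "default",
                             "heart rate gain on arterial pressure error"),
    "baro_gain_contractility": ParamDef(0.02, "1/mmHg", "default",
                                        "contractility gain on arterial pressure error"),
    "baro_gain_resistance_hp": ParamDef(0.03, "1/mmHg", "default",
                                        "arteriolar resistance gain, high-pressure afferent"),
    "baro_gain_resistance_lp": ParamDef(0.05, "1/mmHg", "default",
                                        "arteriolar resistance gain, low-pressure (cardiopulmonary) afferent"),
    "baro_gain_vu_hp": ParamDef(80.0, "mL/mmHg", "default",
                                "venous unstressed-volume gain, high-pressure afferent"),
    "baro_gain_vu_lp": ParamDef(160.0, "mL/mmHg", "default",
                                "venous unstressed-volume gain, low-pressure afferent"),
    "baro_amp_hr": ParamDef(0.5, "-", "default", "heart-rate scaling saturation"),
    "baro_amp_contractility": ParamDef(0.5, "-", "default",
                                       "contractility scaling saturation"),
    "baro_amp_resistance": ParamDef(0.5, "-", "default",
                                    "resistance scaling saturation"),
    "baro_amp_vu": ParamDef(400.0, "mL", "default",
                            "venous unstressed-volume offset saturation"),
    "baro_tau_hr": ParamDef(0.2, "min", "default", "heart-rate time constant"),
    "baro_tau_contractility": ParamDef(0.33, "min", "default",
                                       "contractility time constant"),
    "baro_tau_resistance": ParamDef(0.5, "min", "default",
                                    "resistance time constant"),
    "baro_tau_vu": ParamDef(4.0, "min", "default",
                            "venous unstressed-volume time constant"),
}
PARAMETER_DEFS.update(_circulation_defs())
PARAMETER_DEFS.update(_solute_defs())


class ParameterRegistry(Mapping[str, float]):
    """Flat, typo-safe key->value parameter registry.

    Unknown keys are rejected both at construction and on override, so a
    misspelled config entry fails loudly instead of silently using a default.
    """

    def __init__(self, overrides: Mapping[str, float] | None = None):
        self._values = {k: d.default for k, d in PARAMETER_DEFS.items()}
        if overrides:
            self.update(overrides)

    def update(self, overrides: Mapping[str, float]) -> None:
        unknown = sorted(set(overrides) - set(PARAMETER_DEFS))
        if unknown:
            raise KeyError(f"unknown parameter keys: {unknown}")
        for k, v in overrides.items():
            self._values[k] = float(v)
        self._validate()

    def _validate(self) -> None:
        errors = []
        for k, v in self._values.items():
            if not np.isfinite(v):
                errors.append(f"{k}: non-finite value {v}")
        for k in ("lps", "c_is_compliance_frac", "lp_cell"):
            if self._values[k] <= 0:
                errors.append(f"{k}: must be > 0, got {self._values[k]}")
        for c in COMPARTMENTS:
            if self._values[f"compliance_{c}"] <= 0:
                errors.append(f"compliance_{c}: must be > 0, got "
                              f"{self._values[f'compliance_{c}']}")
        if self._values["q_lymph_normal"] < 0:
            errors.append("q_lymph_normal: must be >= 0")
        alphas = [self._values[f"alpha_{p}"] for p in PORES]
        if abs(sum(alphas) - 1.0) > 1e-12:
            errors.append(f"pore fractions must sum to 1, got {sum(alphas)}")
        if errors:
            raise ValueError("invalid parameter registry:\n  " + "\n  ".join(errors))

    def perturbed(self, key: str, factor: float) -> "ParameterRegistry":
        """Return a copy with ``key`` multiplied by ``factor`` (sensitivity use)."""
        if key not in self._values:
            raise KeyError(key)
        reg = ParameterRegistry()
        reg._values = dict(self._values)
        reg._values[key] = self._values[key] * factor
        return reg

    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)

    def sensitivity_keys(self) -> list[str]:
        """Registry keys eligible for the local sensitivity screen (non-zero)."""
        return [k for k, v in self._values.items() if v != 0.0]


@dataclasses.dataclass
class VirtualPatient:
    """Parameter registry resolved to internal units (mL, min, mmHg, mmol, g)."""

    registry: ParameterRegistry

    # fluid spaces
    v_plasma_n: float = dataclasses.field(init=False)
    v_rbc: float = dataclasses.field(init=False)
    v_is_n: float = dataclasses.field(init=False)
    v_ic_n: float = dataclasses.field(init=False)
    overload: float = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        r = self.registry
        self.v_plasma_n = r["plasma_volume_normal"] * units.L_TO_ML
        hct = r["hematocrit_normal"]
        blood_n = self.v_plasma_n / (1.0 - hct)
        self.v_rbc = blood_n * hct
        self.v_is_n = r["v_is_normal"] * units.L_TO_ML
        self.v_ic_n = r["v_ic_normal"] * units.L_TO_ML
        self.overload = r["fluid_overload"] * units.L_TO_ML

    # -- convenience accessors in internal units ---------------------------
    @property
    def q_lymph_n(self) -> float:
        return units.l_per_day(self.registry["q_lymph_normal"])

    @property
    def lymph_sensitivity(self) -> float:
        return units.ml_per_mmhg_h(self.registry["lymph_sensitivity"])

    @property
    def c_is_compliance(self) -> float:
        """Interstitial compliance, mL/mmHg."""
        return self.registry["c_is_compliance_frac"] * self.v_is_n

    @property
    def v_is_excluded(self) -> float:
        return self.registry["v_is_excluded_frac"] * self.v_is_n

    @property
    def cardiac_output_n(self) -> float:
        return self.registry["cardiac_output_normal"] * units.L_TO_ML

    def compartment_fractions(self) -> np.ndarray:
        f = np.array([self.registry[f"frac_{c}"] for c in COMPARTMENTS])
        return f / f.sum()

    def compartment_compliances(self) -> np.ndarray:
        return np.array([self.registry[f"compliance_{c}"] for c in COMPARTMENTS])

    def compartment_pressures_normal(self) -> np.ndarray:
        return np.array([self.registry[f"pressure_{c}"] for c in COMPARTMENTS])
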