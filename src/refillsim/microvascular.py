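"""Transcapillary physics: oncotic pressures, hydrostatic pressures, lymph
flow and three-pore fluid/protein/solute fluxes.

The capillary wall is represented by three parallel pathways (large pores
~250 A, small pores ~45 A, ultrasmall aquaporin pores ~2 A) sharing the
whole-body hydraulic conductivity LpS (= K_f).  Fluid flux through pore type
``i`` follows the extended Starling relation

    J_v,i = alpha_i * K_f * [ (P_c - P_is)
                              - sum_p sigma_p,i (pi_pl,p - pi_is,p)
                              - sum_s sigma_s,i phi_s (c_pl,s - c_is,s) RT ]

with filtration (plasma -> interstitium) positive.  Oncotic pressures of the
albumin and globulin fractions come from polynomial fits in total protein
concentration; small-solute concentrations are per litre of water, with the
Gibbs-Donnan ion distribution excluded (it is already embedded in the
empirical oncotic polynomials) via fixed per-solute equilibrium offsets.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .units import RT_MMHG_PER_MMOL_L

__all__ = [
    "pi_albumin", "pi_globulin", "pi_total_landis_pappenheimer", "pi_donnan",
    "capillary_pressure", "interstitial_pressure", "lymph_flow",
    "reflection_coefficient", "pore_fluid_flux", "classic_starling_flux",
    "protein_flux", "small_solute_flux", "electroneutrality_adjustment",
    "PoreSystem", "InterstitiumLymphParams", "ProteinFraction", "SmallSolute",
    "StarlingSnapshot",
]


# ---------------------------------------------------------------------------
# oncotic pressures
# ---------------------------------------------------------------------------

def pi_albumin(c_total: float, a: float) -> float:
    """Oncotic pressure (mmHg) of the albumin fraction.

    Parameters
    ----------
    c_total : total protein concentration, g/dL.
    a : albumin mass fraction of total protein.
    """
    c = np.asarray(c_total, dtype=float)
    if np.any(c < 0):
        raise ValueError("total protein concentration must be >= 0")
    return a * (2.8 * c + 0.18 * c**2 + 0.012 * c**3)


def pi_globulin(c_total: float, a: float) -> float:
    """Oncotic pressure (mmHg) of the non-albumin (globulin) fraction."""
    c = np.asarray(c_total, dtype=float)
    if np.any(c < 0):
        raise ValueError("total protein concentration must be >= 0")
    return (1.0 - a) * (1.1 * c + 0.13 * c**2 + 0.005 * c**3)


def pi_total_landis_pappenheimer(c_total: float) -> float:
    """Landis-Pappenheimer total-protein oncotic pressure (mmHg).

    Used by the measurement-style Kr estimator that only sees total plasma
    protein; the forward model uses the per-fraction polynomials instead.
    """
    c = np.asarray(c_total, dtype=float)
    if np.any(c < 0):
        raise ValueError("total protein concentration must be >= 0")
    return 2.1 * c + 0.16 * c**2 + 0.009 * c**3


def pi_donnan(c_total_g_dl: float, a: float,
              z_albumin: float = -17.0, z_globulin: float = -5.0,
              mw_albumin: float = 66.5, mw_globulin: float = 160.0) -> float:
    """Optional additive van't Hoff ion-excess (Donnan) term, mmHg.

    Off by default throughout the model: the empirical oncotic polynomials are
    fits to *measured* colloid osmotic pressure, which already includes the
    Donnan counter-ion excess.  Exposed for exploration.
    """
    c_g_l = np.asarray(c_total_g_dl, dtype=float) * 10.0
    charge = (abs(z_albumin) * a / mw_albumin
              + abs(z_globulin) * (1.0 - a) / mw_globulin) * c_g_l
    return 0.5 * charge * RT_MMHG_PER_MMOL_L


# ---------------------------------------------------------------------------
# hydrostatic pressures and lymph
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class InterstitiumLymphParams:
    """Interstitial pressure-volume law and lymph flow law parameters.

    Internal units: mL, min, mmHg.  ``p_is_excluded`` is the interstitial
    pressure at the protein-excluded volume, where lymph flow ceases.
    """

    p_is_n: float = -1.0          # mmHg
    v_is_n: float = 15000.0       # mL
    compliance: float = 1800.0    # mL/mmHg (12 %/mmHg of 15 L)
    q_lymph_n: float = 8000.0 / 1440.0   # mL/min (8 L/day)
    lymph_sensitivity: float = 43.1 / 60.0  # mL/mmHg/min
    v_is_excluded: float = 7500.0  # mL

    def __post_init__(self) -> None:
        if self.compliance <= 0:
            raise ValueError("interstitial compliance must be > 0")
        if self.v_is_excluded >= self.v_is_n:
            raise ValueError("excluded volume must be below normal volume")
        if self.q_lymph_n < 0:
            raise ValueError("normal lymph flow must be >= 0")

    @property
    def p_is_excluded(self) -> float:
        return self.p_is_n + (self.v_is_excluded - self.v_is_n) / self.compliance


def interstitial_pressure(v_is: float, params: InterstitiumLymphParams) -> float:
    """Interstitial hydrostatic pressure (mmHg), linear in volume (mL)."""
    return params.p_is_n + (np.asarray(v_is, float) - params.v_is_n) / params.compliance


def lymph_flow(p_is: float, params: InterstitiumLymphParams) -> float:
    """Whole-body afferent lymph flow (mL/min).

    Piecewise linear in interstitial pressure: slope ``lymph_sensitivity``
    above the normal pressure, a straight decline to zero at the excluded-
    volume pressure below it, and zero beyond.  Continuous at both knees.
    """
    p = np.asarray(p_is, dtype=float)
    p_ex = params.p_is_excluded
    above = params.q_lymph_n + params.lymph_sensitivity * (p - params.p_is_n)
    below = params.q_lymph_n * (p - p_ex) / (params.p_is_n - p_ex)
    q = np.where(p >= params.p_is_n, above, np.maximum(below, 0.0))
    return q if q.ndim else float(q)


def capillary_pressure(p_sv: float, p_c0: float,
                       w_v: float = 0.8, p_sv0: float = 12.0) -> float:
    """Mean capillary pressure coupled to small-vein pressure.

    The capillary bed autoregulates against arterial pressure changes; a
    fraction ``w_v`` of venous pressure changes is transmitted upstream.
    """
    return p_c0 + w_v * (np.asarray(p_sv, float) - p_sv0)


# ---------------------------------------------------------------------------
# pore system and fluxes
# ---------------------------------------------------------------------------

def reflection_coefficient(r_solute: float, r_pore: float) -> float:
    """Osmotic reflection coefficient from hindered-transport pore theory.

    Uses the classic steric estimate ``sigma = (1 - (1 - lambda)^2)^2`` with
    ``lambda = r_solute / r_pore``, clamped to [0, 1]; solutes larger than the
    pore are fully reflected.
    """
    lam = np.asarray(r_solute, float) / r_pore
    lam = np.clip(lam, 0.0, 1.0)
    phi_part = (1.0 - lam) ** 2
    sig = (1.0 - phi_part) ** 2
    return float(np.clip(sig, 0.0, 1.0)) if np.ndim(sig) == 0 else np.clip(sig, 0.0, 1.0)


@dataclasses.dataclass(frozen=True)
class PoreSystem:
    """Three-pore decomposition of the whole-body capillary wall."""

    radii: tuple[float, float, float] = (250.0, 45.0, 2.0)  # Angstrom
    alphas: tuple[float, float, float] = (0.05, 0.85, 0.10)
    lps: float = 6.0  # mL/min/mmHg
    rt: float = RT_MMHG_PER_MMOL_L

    def __post_init__(self) -> None:
        if abs(sum(self.alphas) - 1.0) > 1e-12:
            raise ValueError("pore conductivity fractions must sum to 1")
        if self.lps <= 0:
            raise ValueError("LpS must be > 0")

    def sigma_protein(self, r_protein: float) -> np.ndarray:
        """Per-pore protein reflection coefficients (ultrasmall pores: 1)."""
        sig = np.array([reflection_coefficient(r_protein, r) for r in self.radii])
        sig[2] = 1.0  # aquaporins are water-exclusive
        return sig

    def sigma_solute(self, r_solute: float) -> np.ndarray:
        sig = np.array([reflection_coefficient(r_solute, r) for r in self.radii])
        sig[2] = 1.0
        return sig


def pore_fluid_flux(pore_index: int,
                    p_c: float, p_is: float,
                    pi_pl: Sequence[float], pi_is: Sequence[float],
                    sigma_protein: np.ndarray,
                    pores: PoreSystem,
                    c_pl_water: Sequence[float] = (),
                    c_is_water: Sequence[float] = (),
                    sigma_solute: np.ndarray | None = None,
                    phi: Sequence[float] = (),
                    donnan_offset: Sequence[float] | None = None) -> float:
    """Fluid flux (mL/min) through one pore type; filtration positive.

    ``sigma_protein``/``sigma_solute`` are ``(n_pores, n_species)`` arrays;
    concentrations are mmol per litre of water.  ``donnan_offset`` holds the
    per-solute equilibrium concentration differences that are excluded from
    the osmotic term (Donnan distribution already folded into the oncotic
    polynomials).
    """
    if not 0 <= pore_index < len(pores.radii):
        raise IndexError(f"unknown pore index {pore_index}")
    dpi = np.dot(np.asarray(sigma_protein)[pore_index],
                 np.asarray(pi_pl, float) - np.asarray(pi_is, float))
    osm = 0.0
    if len(c_pl_water):
        dc = np.asarray(c_pl_water, float) - np.asarray(c_is_water, float)
        if donnan_offset is not None:
            dc = dc - np.asarray(donnan_offset, float)
        osm = np.dot(np.asarray(sigma_solute)[pore_index] * np.asarray(phi, float),
                     dc) * pores.rt
    return pores.alphas[pore_index] * pores.lps * ((p_c - p_is) - dpi - osm)


def classic_starling_flux(p_c: float, p_is: float,
                          pi_pl: float, pi_is: float,
                          sigma: float, k_f: float) -> float:
    """Single-membrane aggregate Starling flux (mL/min), filtration positive."""
    if not 0.0 <= sigma <= 1.0:
        raise ValueError("sigma must lie in [0, 1]")
    return k_f * ((p_c - p_is) - sigma * (pi_pl - pi_is))


def protein_flux(pore_index: int, sigma: float, ps: float,
                 j_v: float, c_pl: float, c_is: float) -> float:
    """Protein mass flux (g/min) through one pore type, plasma -> interstitium.

    Convection uses ``(1 - sigma) * J_v`` with the arithmetic-mean membrane
    concentration; diffusion uses the permeability-surface product.  No
    protein passes through the ultrasmall (water-exclusive) pores.
    """
    if pore_index == 2:
        return 0.0
    c_mean = 0.5 * (c_pl + c_is)
    return (1.0 - sigma) * j_v * c_mean + ps * (c_pl - c_is)


def small_solute_flux(pore_index: int, sigma: float, j_v: float,
                      c_pl_water: float, c_is_water: float,
                      ps: float = 0.0) -> float:
    """Small-solute flux (mmol/min) through one pore type (no adjustment).

    Concentrations in mmol/L water, fluid flux in mL/min: convective term
    ``(1 - sigma) J_v c_mean`` plus diffusion ``ps (c_pl - c_is)``, both
    converted to mmol/min.
    """
    c_mean = 0.5 * (c_pl_water + c_is_water)
    return ((1.0 - sigma) * j_v * c_mean + ps * (c_pl_water - c_is_water)) / 1000.0


def electroneutrality_adjustment(fluxes: np.ndarray, valences: np.ndarray,
                                 carrier: int,
                                 extra_charge_flux: float = 0.0) -> np.ndarray:
    """Set the carrier species' flux so the summed charge flux is zero.

    ``extra_charge_flux`` carries charge moved by species outside ``fluxes``
    (the charged plasma proteins, in mEq/min).  Raises if the carrier valence
    is zero.
    """
    z = np.asarray(valences, float)
    if z[carrier] == 0:
        raise ValueError("electroneutrality carrier must be charged")
    adjusted = np.array(fluxes, dtype=float)
    others = np.dot(np.delete(z, carrier), np.delete(adjusted, carrier))
    adjusted[carrier] = -(others + extra_charge_flux) / z[carrier]
    return adjusted


# ---------------------------------------------------------------------------
# descriptive containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ProteinFraction:
    """One plasma protein fraction (albumin or collective globulins)."""

    name: str
    mass_plasma: float          # g
    mass_interstitial: float    # g
    albumin_fraction_plasma: float
    albumin_fraction_is: float
    sigma: np.ndarray           # per-pore reflection coefficients
    ps: np.ndarray              # per-pore diffusive PS, mL/min

    def __post_init__(self) -> None:
        if self.mass_plasma < 0 or self.mass_interstitial < 0:
            raise ValueError("protein masses must be >= 0")
        if np.any(self.sigma < 0) or np.any(self.sigma > 1):
            raise ValueError("reflection coefficients must lie in [0, 1]")
        for a in (self.albumin_fraction_plasma, self.albumin_fraction_is):
            if not 0.0 < a < 1.0:
                raise ValueError("albumin fraction must lie in (0, 1)")


@dataclasses.dataclass(frozen=True)
class SmallSolute:
    """One small solute tracked in plasma, interstitial and cell water."""

    name: str
    valence: int
    phi: float
    n_plasma: float          # mmol in plasma water
    n_interstitial: float    # mmol
    n_intracellular: float   # mmol
    sigma: np.ndarray        # per-pore reflection coefficients
    clearance: float = 0.0   # mL/min
    c_dialysate: float = 0.0  # mmol/L
    alpha_dialyzer: float = 1.0
    is_carrier: bool = False

    def __post_init__(self) -> None:
        if min(self.n_plasma, self.n_interstitial, self.n_intracellular) < 0:
            raise ValueError("solute amounts must be >= 0")
        if np.any(self.sigma < 0) or np.any(self.sigma > 1):
            raise ValueError("reflection coefficients must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class StarlingSnapshot:
    """Instantaneous Starling-force and flux decomposition."""

    p_c: float
    p_is: float
    pi_pl: np.ndarray        # per protein fraction, mmHg
    pi_is: np.ndarray
    osmotic_term: np.ndarray  # per pore, mmHg
    j_v: np.ndarray           # per pore, mL/min (filtration positive)
    q_lymph: float

    @property
    def j_v_total(self) -> float:
        return float(np.sum(self.j_v))

    @property
    def pi_pl_total(self) -> float:
        return float(np.sum(self.pi_pl))

    @property
    def pi_is_total(self) -> float:
        return float(np.sum(self.pi_is))
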