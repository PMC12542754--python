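"""Acid–base speciation and charge balance for dilute hot-spring waters.

Measured total concentrations (Table-style major-ion analyses) are resolved
into free species using temperature-corrected dissociation constants and
extended Debye–Hückel activity coefficients,

    log10(gamma_i) = -A z_i^2 sqrt(I) / (1 + B a_i sqrt(I)),

with the Debye–Hückel A and B parameters interpolated from standard
tabulations over 0–60 °C and Kielland ion-size parameters a_i. Ion pairs
(CaSO4(aq), MgSO4(aq), ...) are deliberately omitted: at the ionic strengths
of these waters (I < 0.02 mol/kg) the model reproduces full speciation-code
results at the few-percent / ~0.05 pH-unit level, which is the accuracy this
package claims.

Monoprotic couples use a van 't Hoff temperature correction of the 25 °C
pKa; the carbonate system uses the empirical freshwater polynomials of
Harned & Davis (pK1) and Harned & Scholes (pK2), valid 0–50 °C. pH is
treated as -log10 of the H+ *activity*; the H+ concentration entering the
charge balance is activity / gamma(H+).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import brentq

from .errors import ComputationError, DataError, UsageError

# ---------------------------------------------------------------------------
# constants
# ---------------------------------------------------------------------------

#: Debye–Hückel limiting-law parameters vs temperature (°C), standard values
#: for water (A in kg^1/2 mol^-1/2, B in 10^8 kg^1/2 mol^-1/2 cm^-1 == 1/Å).
_DH_TEMPS = np.array([0.0, 10.0, 20.0, 25.0, 30.0, 40.0, 50.0, 60.0])
_DH_A = np.array([0.4883, 0.4960, 0.5042, 0.5085, 0.5130, 0.5221, 0.5319, 0.5425])
_DH_B = np.array([0.3241, 0.3258, 0.3273, 0.3281, 0.3290, 0.3305, 0.3321, 0.3338])

#: Kielland ion-size parameters, Å
ION_SIZES: dict[str, float] = {
    "H+": 9.0, "Li+": 6.0, "Na+": 4.0, "K+": 3.0, "NH4+": 2.5,
    "Mg+2": 8.0, "Ca+2": 6.0, "Fe+2": 6.0,
    "Cl-": 3.0, "F-": 3.5, "Br-": 3.0, "NO3-": 3.0, "OH-": 3.5,
    "SO4-2": 4.0, "HSO4-": 4.5, "HCO3-": 4.5, "CO3-2": 4.5,
    "CH3COO-": 4.5, "HCOO-": 3.5,
}
DEFAULT_ION_SIZE = 4.0

GAS_CONSTANT_KJ = 8.314462618e-3  # kJ mol^-1 K^-1
T0_K = 298.15


_CHARGE_RE = re.compile(r"([+-])(\d?)$")


def charge_of(species: str) -> int:
    """Integer charge parsed from a species label ('SO4-2' -> -2)."""
    m = _CHARGE_RE.search(species)
    if not m:
        return 0
    sign = 1 if m.group(1) == "+" else -1
    return sign * int(m.group(2) or 1)


@dataclass(frozen=True)
class AcidBaseCouple:
    """A monoprotic acid/base pair with a van 't Hoff temperature proxy.

    ``dH_kJ`` is the standard enthalpy of the dissociation reaction
    HA -> H+ + A-; positive dH makes the acid stronger (lower pKa) at higher
    temperature.
    """

    name: str
    acid: str
    base: str
    acid_charge: int
    pKa_25: float
    dH_kJ: float = 0.0

    def __post_init__(self) -> None:
        if charge_of(self.base) != charge_of(self.acid) - 1:
            raise DataError(f"{self.name}: base charge must be acid charge - 1")


#: default couples; 25 °C pKa values from standard compilations
DEFAULT_COUPLES: tuple[AcidBaseCouple, ...] = (
    AcidBaseCouple("acetate", "CH3COOH", "CH3COO-", 0, 4.756, -0.41),
    AcidBaseCouple("formate", "HCOOH", "HCOO-", 0, 3.745, -0.04),
    AcidBaseCouple("sulfate", "HSO4-", "SO4-2", -1, 1.99, -22.4),
    AcidBaseCouple("ammonium", "NH4+", "NH3", 1, 9.25, 52.2),
    AcidBaseCouple("fluoride", "HF", "F-", 0, 3.17, -13.3),
)

#: components whose measured total is distributed over an acid/base couple
COMPONENT_COUPLES: dict[str, str] = {
    "SO4-2": "sulfate", "acetate": "acetate", "formate": "formate",
    "NH4+": "ammonium", "F-": "fluoride",
}

#: components carried as single free ions
CONSERVATIVE_COMPONENTS = ("Na+", "K+", "Li+", "Mg+2", "Ca+2", "Fe+2",
                           "Cl-", "Br-", "NO3-")

@dataclass
class WaterComposition:
    """Measured bulk composition of a water sample.

    ``totals`` maps component labels to total concentrations in mol/L
    (molarity ~ molality at these dilutions; no density correction).
    """

    temperature_c: float
    totals: dict[str, float] = field(default_factory=dict)
    field_pH: Optional[float] = None
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.temperature_c <= 100.0:
            raise DataError("temperature must be in [0, 100] °C")
        for comp, tot in self.totals.items():
            if tot < 0:
                raise DataError(f"negative total for {comp}")


@dataclass
class SpeciationResult:
    """Resolved species for one water at one pH."""

    pH: float
    temperature_c: float
    species: dict[str, float]            # molalities, mol/kg
    activity_coefficients: dict[str, float]
    ionic_strength: float
    fractions: dict[str, dict[str, float]]  # component -> species -> fraction
    iterations: int


# ---------------------------------------------------------------------------
# equilibrium constants
# ---------------------------------------------------------------------------

def pKa_at_temperature(couple: AcidBaseCouple, temperature_c: float) -> float:
    """van 't Hoff correction of the 25 °C pKa to ``temperature_c``."""
    if not 0.0 <= temperature_c <= 100.0:
        raise UsageError("temperature must be in [0, 100] °C")
    T = temperature_c + 273.15
    return couple.pKa_25 + couple.dH_kJ / (GAS_CONSTANT_KJ * math.log(10)) * (
        1.0 / T - 1.0 / T0_K)


def carbonate_pK1(temperature_c: float) -> float:
    """First carbonate dissociation, freshwater scale (Harned & Davis)."""
    T = temperature_c + 273.15
    return 3404.71 / T + 0.032786 * T - 14.8435


def carbonate_pK2(temperature_c: float) -> float:
    """Second carbonate dissociation (Harned & Scholes)."""
    T = temperature_c + 273.15
    return 2902.39 / T + 0.02379 * T - 6.4980


def water_pKw(temperature_c: float) -> float:
    """Ion product of water (Harned & Owen fit)."""
    T = temperature_c + 273.15
    return 4470.99 / T + 0.017060 * T - 6.0875


# ---------------------------------------------------------------------------
# activities
# ---------------------------------------------------------------------------

def debye_huckel_params(temperature_c: float) -> tuple[float, float]:
    """Interpolated extended Debye–Hückel A and B at a temperature."""
    A = float(np.interp(temperature_c, _DH_TEMPS, _DH_A))
    B = float(np.interp(temperature_c, _DH_TEMPS, _DH_B))
    return A, B


def ionic_strength(molalities: Mapping[str, float],
                   charges: Optional[Mapping[str, int]] = None) -> float:
    """I = 1/2 sum m_i z_i^2 over all charged species, mol/kg."""
    z = charges if charges is not None else {s: charge_of(s) for s in molalities}
    return 0.5 * sum(m * z[s] ** 2 for s, m in molalities.items())


def activity_coefficient(z: int, ionic_strength_molal: float, temperature_c: float,
                         ion_size_angstrom: float = DEFAULT_ION_SIZE) -> float:
    """Extended Debye–Hückel activity coefficient; 1 for neutral species."""
    if ionic_strength_molal < 0:
        raise DataError("ionic strength must be >= 0")
    if z == 0 or ionic_strength_molal == 0:
        return 1.0
    A, B = debye_huckel_params(temperature_c)
    sqrt_i = math.sqrt(ionic_strength_molal)
    log_gamma = -A * z * z * sqrt_i / (1.0 + B * ion_size_angstrom * sqrt_i)
    return 10.0 ** log_gamma


def fraction_protonated(pH: float, pKa: float, gamma_acid: float = 1.0,
                        gamma_base: float = 1.0) -> float:
    """Fraction of a monoprotic couple in the protonated (acid) form.

    The ideal Henderson–Hasselbalch form is f = 1 / (1 + 10^(pH - pKa));
    supplying activity coefficients gives the activity-corrected variant,
    with the base/acid molality ratio Ka * gamma_acid / (gamma_base * a_H+).
    """
    ratio = 10.0 ** (pH - pKa) * gamma_acid / gamma_base
    return 1.0 / (1.0 + ratio)


# ---------------------------------------------------------------------------
# speciation
# ---------------------------------------------------------------------------

def _gamma_for(species: str, I: float, temperature_c: float) -> float:
    return activity_coefficient(charge_of(species), I, temperature_c,
                                ION_SIZES.get(species, DEFAULT_ION_SIZE))

_MAX_ITER = 100
_I_RTOL = 1e-10


def speciate(composition: WaterComposition, pH: Optional[float] = None,
             couples: tuple[AcidBaseCouple, ...] = DEFAULT_COUPLES) -> SpeciationResult:
    """Distribute measured totals over species at a given pH.

    Activity coefficients and ionic strength are iterated to a fixed point
    (relative tolerance 1e-10 on I, at most 100 iterations). Mass balance is
    exact by construction: each component's species are fractions of its
    measured total.
    """
    if pH is None:
        pH = composition.field_pH
    if pH is None:
        raise UsageError("no pH supplied and composition has no field pH")
    T = composition.temperature_c
    couple_map = {c.name: c for c in couples}
    a_h = 10.0 ** (-pH)
    pKw = water_pKw(T)
    pk1, pk2 = carbonate_pK1(T), carbonate_pK2(T)

    I = 0.0
    species: dict[str, float] = {}
    fractions: dict[str, dict[str, float]] = {}
    for it in range(1, _MAX_ITER + 1):
        species = {}
        fractions = {}
        for comp in CONSERVATIVE_COMPONENTS:
            tot = composition.totals.get(comp, 0.0)
            if tot > 0:
                species[comp] = species.get(comp, 0.0) + tot
                fractions[comp] = {comp: 1.0}
        for comp, couple_name in COMPONENT_COUPLES.items():
            tot = composition.totals.get(comp, 0.0)
            if tot <= 0:
                continue
            c = couple_map[couple_name]
            pka = pKa_at_temperature(c, T)
            g_acid = _gamma_for(c.acid, I, T)
            g_base = _gamma_for(c.base, I, T)
            f_acid = fraction_protonated(pH, pka, g_acid, g_base)
            m_acid = tot * f_acid
            m_base = tot - m_acid
            species[c.acid] = species.get(c.acid, 0.0) + m_acid
            species[c.base] = species.get(c.base, 0.0) + m_base
            fractions[comp] = {c.acid: f_acid, c.base: 1.0 - f_acid}
        dic = composition.totals.get("DIC", 0.0)
        if dic > 0:
            g_hco3 = _gamma_for("HCO3-", I, T)
            g_co3 = _gamma_for("CO3-2", I, T)
            r1 = 10.0 ** (-pk1) / (g_hco3 * a_h)        # HCO3-/CO2 molality ratio
            r2 = 10.0 ** (-pk2) * g_hco3 / (g_co3 * a_h)  # CO3-2/HCO3- ratio
            denom = 1.0 + r1 + r1 * r2
            m_co2 = dic / denom
            m_hco3 = m_co2 * r1
            m_co3 = m_hco3 * r2
            species["CO2(aq)"] = m_co2
            species["HCO3-"] = m_hco3
            species["CO3-2"] = m_co3
            fractions["DIC"] = {"CO2(aq)": m_co2 / dic, "HCO3-": m_hco3 / dic,
                                "CO3-2": m_co3 / dic}
        species["H+"] = a_h / _gamma_for("H+", I, T)
        species["OH-"] = 10.0 ** (pH - pKw) / _gamma_for("OH-", I, T)

        I_new = ionic_strength(species)
        if abs(I_new - I) <= _I_RTOL * max(I_new, 1e-30):
            I = I_new
            break
        I = I_new
    else:
        raise ComputationError(
            f"activity-coefficient iteration did not converge; last I = {I}")

    gammas = {s: _gamma_for(s, I, T) for s in species}
    return SpeciationResult(pH=pH, temperature_c=T, species=species,
                            activity_coefficients=gammas, ionic_strength=I,
                            fractions=fractions, iterations=it)


def charge_imbalance(result: SpeciationResult) -> float:
    """Charge imbalance as percent of the mean charge.

    CI% = 100 * (sum cation eq - sum anion eq) / (mean of the two sums).
    H+ and OH- are included via their molalities in the speciation result.
    """
    cations = sum(m * z for s, m in result.species.items()
                  if (z := charge_of(s)) > 0)
    anions = sum(m * -z for s, m in result.species.items()
                 if (z := charge_of(s)) < 0)
    mean = 0.5 * (cations + anions)
    if mean == 0:
        raise ComputationError("solution carries no charge")
    return 100.0 * (cations - anions) / mean


def solve_ph_charge_balance(composition: WaterComposition,
                            couples: tuple[AcidBaseCouple, ...] = DEFAULT_COUPLES,
                            bracket: tuple[float, float] = (0.0, 12.0)
                            ) -> tuple[float, SpeciationResult]:
    """pH at which the charge imbalance vanishes, by bracketed root-finding.

    Re-speciates the composition at every trial pH; the imbalance is a
    strictly decreasing function of pH (H+ falls, carbonate/acid anions
    rise), so Brent's method on the bracket is robust. Raises
    :class:`ComputationError` with the endpoint imbalances if the
    composition cannot balance inside the bracket.
    """
    if not any(t > 0 for t in composition.totals.values()):
        raise ComputationError("composition has no components to balance")

    def imbalance(ph: float) -> float:
        return charge_imbalance(speciate(composition, pH=ph, couples=couples))

    lo, hi = bracket
    f_lo, f_hi = imbalance(lo), imbalance(hi)
    if f_lo * f_hi > 0:
        raise ComputationError(
            "composition cannot reach charge balance in pH bracket "
            f"[{lo}, {hi}]: imbalance {f_lo:.3g}% at pH {lo}, "
            f"{f_hi:.3g}% at pH {hi}")
    ph = float(brentq(imbalance, lo, hi, xtol=1e-10, rtol=8.9e-16))
    return ph, speciate(composition, pH=ph, couples=couples)
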