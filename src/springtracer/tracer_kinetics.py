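"""Radiotracer (14C) microcosm rate estimation.

Converts liquid-scintillation counts to carbon assimilation/dissimilation
rates for light/dark/killed microcosm incubations. The core quantity is the
zero-order substrate conversion rate

    rate [mg C (g C)^-1 h^-1] =
        (DPM_T - DPM_K) * mmol_substrate * M_C * nu_C * alpha
        / (DPM_added * gdw * (wt%C / 100) * t * F_s)

where DPM_T and DPM_K are the mean disintegrations per minute recovered from
treatment and killed-control vials, mmol_substrate is the total (native +
labeled) substrate pool, M_C the molar mass of carbon, nu_C the carbons per
substrate molecule, alpha the isotopic discrimination factor correcting for
the slower uptake of 14C relative to 12C, DPM_added the spike activity, gdw
the dry mass of mat material, wt%C its carbon content, t the incubation
duration and F_s the fraction of the assay sampled for counting (1 for
filter-captured biomass, 0.25 for the headspace-CO2 capture used for
dissimilation). Uncertainties are propagated to first order through every
factor; replicate-to-replicate variation of the counts is the dominant term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ComputationError, ConfigurationError, DataError, UsageError
from .uncertainty import UFloat, as_ufloat

#: molar mass of carbon, g/mol
MOLAR_MASS_C = 12.011
#: disintegrations per minute per microcurie (definition of the curie)
DPM_PER_UCI = 2.22e6
#: default isotopic discrimination factor for 14C uptake
DEFAULT_ALPHA = 1.05


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuenchCurve:
    """Counting-efficiency calibration of a liquid scintillation counter.

    ``points`` maps a quench indicator (e.g. the transformed spectral index
    of the external standard) to the counting efficiency measured on quenched
    standards. Efficiency at an arbitrary indicator value is obtained by
    piecewise-linear interpolation; indicators outside the calibrated range
    are clipped to the nearest endpoint.
    """

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ConfigurationError("a quench curve needs at least 2 points")
        q = [p[0] for p in self.points]
        e = [p[1] for p in self.points]
        if any(b <= a for a, b in zip(q, q[1:])):
            raise ConfigurationError("quench-indicator values must be strictly increasing")
        if any(not 0 < eff <= 1 for eff in e):
            raise DataError("counting efficiencies must be in (0, 1]")

    def efficiency(self, quench_indicator: float) -> float:
        q = np.array([p[0] for p in self.points])
        e = np.array([p[1] for p in self.points])
        return float(np.interp(quench_indicator, q, e))

    @classmethod
    def constant(cls, efficiency: float) -> "QuenchCurve":
        """A flat curve for counters reporting a single efficiency."""
        return cls(((0.0, efficiency), (1.0, efficiency)))


@dataclass
class MicrocosmVial:
    """One sealed incubation bottle of the field assay."""

    vial_id: str
    substrate: str                       # "DIC" or "acetate"
    treatment: str                       # "light", "dark" or "killed"
    water_volume_ml: float
    slurry_volume_ml: float
    spike_volume_ml: float
    amendment_volumes_ml: Mapping[str, float] = field(default_factory=dict)
    measured_cpm: Optional[float] = None
    measured_dpm: Optional[float] = None
    quench_indicator: Optional[float] = None
    assay_mode: str = "assimilation"     # or "dissimilation"

    def __post_init__(self) -> None:
        if self.substrate not in ("DIC", "acetate"):
            raise DataError(f"unknown substrate {self.substrate!r}")
        if self.treatment not in ("light", "dark", "killed"):
            raise DataError(f"unknown treatment {self.treatment!r}")
        if self.assay_mode not in ("assimilation", "dissimilation"):
            raise DataError(f"unknown assay mode {self.assay_mode!r}")
        vols = [self.water_volume_ml, self.slurry_volume_ml, self.spike_volume_ml,
                *self.amendment_volumes_ml.values()]
        if any(v < 0 for v in vols):
            raise DataError(f"vial {self.vial_id}: volumes must be >= 0")
        if self.treatment == "killed" and "HgCl2" not in self.amendment_volumes_ml:
            raise DataError(f"killed vial {self.vial_id} lacks an HgCl2 amendment")

    @property
    def liquid_volume_ml(self) -> float:
        """Total liquid in the vial (water + slurry + spike + amendments)."""
        return (self.water_volume_ml + self.slurry_volume_ml + self.spike_volume_ml
                + sum(self.amendment_volumes_ml.values()))


@dataclass(frozen=True)
class TracerSpike:
    """A 14C-labeled substrate addition."""

    substrate: str
    activity_added_uCi: float
    specific_activity_mCi_per_mmol: float
    carbons_per_molecule: int

    def __post_init__(self) -> None:
        if self.activity_added_uCi <= 0:
            raise DataError("spike activity must be > 0")
        if self.specific_activity_mCi_per_mmol <= 0:
            raise DataError("specific activity must be > 0")
        if self.carbons_per_molecule not in (1, 2):
            raise DataError("carbons per molecule must be 1 or 2")

    @property
    def dpm_added(self) -> float:
        return self.activity_added_uCi * DPM_PER_UCI

    @property
    def mmol_added(self) -> float:
        """mmol of labeled compound: uCi -> mCi, divided by specific activity."""
        return self.activity_added_uCi * 1e-3 / self.specific_activity_mCi_per_mmol


@dataclass(frozen=True)
class BiomassAliquot:
    """Dry mass and elemental content of the mat material in a vial."""

    dry_mass_g: UFloat
    wt_pct_C: UFloat
    wt_pct_N: UFloat = UFloat(0.0)

    def __post_init__(self) -> None:
        if self.dry_mass_g.value <= 0:
            raise DataError("dry mass must be > 0")
        if not 0 < self.wt_pct_C.value <= 100:
            raise DataError("wt% C must be in (0, 100]")
        if self.wt_pct_N.value < 0:
            raise DataError("wt% N must be >= 0")


@dataclass(frozen=True)
class RateInputs:
    """Every symbol of the rate equation, with uncertainties."""

    dpm_T: UFloat                 # mean treatment DPM ± sd of the mean
    dpm_K: UFloat                 # mean killed-control DPM ± sd of the mean
    mmol_substrate: UFloat        # total (native + labeled) substrate, mmol
    dpm_added: UFloat             # spike activity, DPM
    gdw: UFloat                   # dry mass of mat material, g
    wt_pct_C: UFloat              # carbon content of the mat, % of dry mass
    t_hours: float                # incubation duration
    F_s: float = 1.0              # fraction sampled for counting
    nu_C: int = 1                 # carbons per substrate molecule
    alpha: float = DEFAULT_ALPHA  # isotopic discrimination factor
    M_C: float = MOLAR_MASS_C     # molar mass of carbon, g/mol

    def __post_init__(self) -> None:
        if self.t_hours <= 0:
            raise DataError("incubation duration must be > 0")
        if not 0 < self.F_s <= 1:
            raise DataError("F_s must be in (0, 1]")
        if self.alpha <= 0:
            raise DataError("alpha must be > 0")


@dataclass(frozen=True)
class RateResult:
    """A computed conversion rate, mg C (g C)^-1 h^-1."""

    rate: UFloat
    net_dpm: float
    distinguishable_from_zero: bool
    substrate: Optional[str] = None
    assay_mode: Optional[str] = None


@dataclass(frozen=True)
class TreatmentComparison:
    """One-sided Welch t-test of light > dark replicate rates."""

    significant: bool
    p_value: float
    alpha_level: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def dpm_from_cpm(cpm: float, background_cpm: float, curve: QuenchCurve,
                 quench_indicator: float) -> float:
    """Convert counts per minute to disintegrations per minute.

    Background is subtracted first (never below zero) and the net counts are
    divided by the quench-curve counting efficiency at the vial's quench
    indicator.
    """
    if cpm < 0:
        raise DataError("cpm must be >= 0")
    eff = curve.efficiency(quench_indicator)
    if eff <= 0:
        raise DataError("counting efficiency must be > 0")
    return max(cpm - background_cpm, 0.0) / eff


def headspace_fraction(bottle_full_mass_g: float, bottle_empty_mass_g: float,
                       water_density_g_per_ml: float, liquid_solid_volume_ml: float,
                       syringe_volume_ml: float) -> float:
    """Fraction of the vial headspace sampled by syringe withdrawal (F_s).

    The sealed-bottle volume is obtained gravimetrically (mass of the bottle
    filled with deionized water minus the empty mass, over the water
    density). After withdrawal the headspace gas occupies the residual
    headspace plus the syringe, so the sampled fraction is
    ``syringe / (headspace + syringe)``.
    """
    if bottle_full_mass_g <= bottle_empty_mass_g:
        raise DataError("full bottle mass must exceed empty mass")
    bottle_volume = (bottle_full_mass_g - bottle_empty_mass_g) / water_density_g_per_ml
    headspace = bottle_volume - liquid_solid_volume_ml
    if headspace <= 0:
        raise DataError("liquid/solid volume leaves no headspace")
    return syringe_volume_ml / (headspace + syringe_volume_ml)


def total_substrate_mmol(native_concentration_mol_per_l: UFloat | float,
                         native_volume_ml: float,
                         spike: Optional[TracerSpike]) -> UFloat:
    """Total substrate pool (native + labeled) in a microcosm, mmol.

    ``native_volume_ml`` is the liquid volume carrying substrate at the
    spring-water concentration (water + slurry liquid). ``spike=None``
    leaves the native pool unchanged.
    """
    conc = as_ufloat(native_concentration_mol_per_l)
    if conc.value < 0 or native_volume_ml < 0:
        raise DataError("concentration and volume must be >= 0")
    native_mmol = conc * native_volume_ml  # mol/L * mL == mmol
    if spike is None:
        return native_mmol
    return native_mmol + spike.mmol_added


def assimilation_rate(inputs: RateInputs, confidence: float = 0.95) -> RateResult:
    """Evaluate the rate equation with first-order uncertainty propagation.

    A negative net DPM (killed control exceeding the treatment) is reported
    as a negative rate with ``distinguishable_from_zero=False`` rather than
    clipped, so that light-minus-dark differences remain unbiased.
    """
    for name, u in (("dpm_added", inputs.dpm_added), ("gdw", inputs.gdw),
                    ("wt_pct_C", inputs.wt_pct_C)):
        if u.value == 0:
            raise ComputationError(f"{name} must be non-zero")
    net = inputs.dpm_T - inputs.dpm_K
    numerator = net * inputs.mmol_substrate * inputs.M_C * inputs.nu_C * inputs.alpha
    denominator = (inputs.dpm_added * inputs.gdw * (inputs.wt_pct_C / 100.0)
                   * inputs.t_hours * inputs.F_s)
    rate = numerator / denominator
    z = stats.norm.ppf(confidence)  # one-sided
    distinguishable = net.value > 0 and rate.value > z * rate.sd
    return RateResult(rate=rate, net_dpm=net.value,
                      distinguishable_from_zero=bool(distinguishable))


def dissimilation_rate(inputs: RateInputs, confidence: float = 0.95) -> RateResult:
    """Rate of substrate oxidation to CO2 captured from the vial headspace.

    Identical arithmetic to :func:`assimilation_rate`; only the provenance of
    the DPM (CO2 absorbed into alkaline scintillant from a syringe headspace
    sample) and the sampled fraction F_s (typically 0.25) differ.
    """
    res = assimilation_rate(inputs, confidence=confidence)
    return RateResult(rate=res.rate, net_dpm=res.net_dpm,
                      distinguishable_from_zero=res.distinguishable_from_zero,
                      assay_mode="dissimilation")


def light_driven_rate(light: RateResult, dark: RateResult) -> RateResult:
    """Light-minus-dark rate difference, errors combined in quadrature.

    A dark rate exceeding the light rate yields a negative difference; the
    sign is preserved.
    """
    if (light.substrate is not None and dark.substrate is not None
            and light.substrate != dark.substrate):
        raise UsageError("light and dark results are for different substrates")
    if (light.assay_mode is not None and dark.assay_mode is not None
            and light.assay_mode != dark.assay_mode):
        raise UsageError("light and dark results are for different assay modes")
    diff = light.rate - dark.rate
    distinguishable = diff.value > 0 and (diff.sd == 0 or diff.value > 1.645 * diff.sd)
    return RateResult(rate=diff, net_dpm=light.net_dpm - dark.net_dpm,
                      distinguishable_from_zero=bool(distinguishable),
                      substrate=light.substrate, assay_mode=light.assay_mode)


def compare_treatments(light_rates: Sequence[float], dark_rates: Sequence[float],
                       alpha_level: float = 0.05) -> TreatmentComparison:
    """One-sided Welch t-test of H1: mean(light) > mean(dark).

    Welch's unequal-variance form is used because light and dark microcosms
    need not share a variance. Zero-variance degenerate groups are handled
    without failure: equal constant groups give p = 0.5, otherwise p is 0 or
    1 according to the direction of the difference.
    """
    if len(light_rates) < 2 or len(dark_rates) < 2:
        raise UsageError("need at least 2 replicates per group")
    light = np.asarray(light_rates, dtype=float)
    dark = np.asarray(dark_rates, dtype=float)
    if light.std(ddof=1) == 0 and dark.std(ddof=1) == 0:
        if light.mean() == dark.mean():
            p = 0.5
        else:
            p = 0.0 if light.mean() > dark.mean() else 1.0
    else:
        p = float(stats.ttest_ind(light, dark, equal_var=False,
                                  alternative="greater").pvalue)
    return TreatmentComparison(significant=bool(p < alpha_level), p_value=p,
                               alpha_level=alpha_level)


def _c4(n: int) -> float:
    """Unbiasing constant for the sample standard deviation, E[s] = c4 * sigma."""
    return math.sqrt(2.0 / (n - 1)) * math.gamma(n / 2) / math.gamma((n - 1) / 2)


def replicate_mean(dpms: Sequence[float]) -> UFloat:
    """Mean DPM over replicate vials ± standard deviation of the mean.

    Triplicate designs leave very few degrees of freedom, where the sample
    standard deviation is a biased (low) estimator of sigma; the c4
    correction (E[s] = c4 * sigma, c4(3) ~ 0.886) removes that bias so the
    propagated rate uncertainties stay calibrated. With a single replicate
    the scatter term is unavailable and the sd is 0; downstream significance
    is then reported as unavailable.
    """
    arr = np.asarray(dpms, dtype=float)
    if arr.size == 0:
        raise DataError("no replicates")
    if arr.size == 1:
        return UFloat(float(arr[0]), 0.0)
    sd = arr.std(ddof=1) / _c4(arr.size) / math.sqrt(arr.size)
    return UFloat(float(arr.mean()), float(sd))
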