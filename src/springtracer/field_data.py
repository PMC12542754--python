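"""Bundled field measurements from the Yellowstone springs that motivated
this package.

Four water/biomass analyses: the warm acidic spring at Amphitheater Springs
(sampled 2017 and 2014), the background reach of Lemonade Creek upstream of
the spring, and a spring in Hot Spring Basin. Concentrations are bulk
analytical totals in mol/L; temperatures in °C; isotope ratios in ‰ (vs
VPDB for carbon, vs air for nitrogen). These are the worked-example inputs
for the speciation, charge-balance and isotope-budget operations.
"""

from __future__ import annotations

from .aqueous_speciation import WaterComposition
from .isotope_budget import IsotopeTable
from .uncertainty import UFloat


def amphitheater_2017() -> WaterComposition:
    return WaterComposition(
        sample_id="amphitheater_2017",
        temperature_c=35.4,
        field_pH=3.76,
        totals={
            "F-": 3.1e-6, "Cl-": 7.9e-5, "Br-": 1.3e-7, "SO4-2": 1.0e-3,
            "NO3-": 1.3e-7, "Li+": 3.1e-6, "Na+": 9.7e-4, "K+": 4.3e-4,
            "Mg+2": 5.6e-5, "Ca+2": 1.3e-4, "NH4+": 3.2e-5, "Fe+2": 5.7e-5,
            "formate": 2.5e-6, "acetate": 8.3e-7, "DIC": 1.1e-2,
        },
    )


def amphitheater_2014() -> WaterComposition:
    return WaterComposition(
        sample_id="amphitheater_2014",
        temperature_c=38.0,
        field_pH=3.52,
        totals={
            "F-": 6.5e-6, "Cl-": 1.0e-4, "Br-": 1.2e-7, "SO4-2": 1.3e-3,
            "NO3-": 9.3e-7, "Li+": 4.0e-6, "Na+": 1.2e-3, "K+": 5.3e-4,
            "Mg+2": 7.5e-5, "Ca+2": 1.8e-4, "NH4+": 3.4e-5, "Fe+2": 5.3e-5,
            "DIC": 7.9e-3,
        },
    )


def lemonade_creek() -> WaterComposition:
    return WaterComposition(
        sample_id="lemonade_creek",
        temperature_c=12.6,
        field_pH=5.28,
        totals={
            "F-": 2.6e-6, "Cl-": 1.6e-5, "Br-": 3.2e-8, "SO4-2": 5.8e-5,
            "NO3-": 1.5e-7, "Li+": 1.7e-7, "Na+": 8.2e-5, "K+": 4.5e-5,
            "Mg+2": 3.4e-5, "Ca+2": 7.3e-5, "NH4+": 4.1e-7, "Fe+2": 3.6e-7,
            "DIC": 2.1e-3,
        },
    )


def hot_spring_basin() -> WaterComposition:
    return WaterComposition(
        sample_id="hot_spring_basin",
        temperature_c=37.2,
        field_pH=2.95,
        totals={
            "F-": 2.2e-5, "Cl-": 2.1e-5, "Br-": 6.0e-8, "SO4-2": 4.2e-3,
            "NO3-": 6.2e-7, "Li+": 3.0e-6, "Na+": 1.1e-3, "K+": 5.8e-4,
            "Mg+2": 1.1e-4, "Ca+2": 2.3e-4, "NH4+": 2.8e-4, "Fe+2": 5.0e-5,
            "formate": 2.3e-6, "acetate": 9.9e-7, "DIC": 6.0e-3,
        },
    )


def isotope_tables() -> dict[str, IsotopeTable]:
    """Mat biomass / DIC isotope and elemental measurements per site."""
    return {
        "amphitheater_2017": IsotopeTable(
            d13C_mat=UFloat(-26.4, 0.1), d13C_DIC=UFloat(-3.5, 0.2),
            d13C_DOC=UFloat(-25.4, 0.2),
            wt_pct_C=UFloat(9.11, 0.07), wt_pct_N=UFloat(1.315, 0.007),
            d15N_mat=UFloat(-2.8, 0.1)),
        "amphitheater_2014": IsotopeTable(
            d13C_mat=UFloat(-26.1, 0.1), d13C_DIC=UFloat(-4.3, 0.2),
            d13C_DOC=UFloat(-24.5, 0.3),
            wt_pct_C=UFloat(10.63, 0.07), wt_pct_N=UFloat(1.355, 0.005),
            d15N_mat=UFloat(-4.9, 0.1)),
        "hot_spring_basin": IsotopeTable(
            d13C_mat=UFloat(-25.6, 0.1), d13C_DIC=UFloat(-3.5, 0.2),
            d13C_DOC=UFloat(-25.4, 0.6),
            wt_pct_C=UFloat(12.0, 0.3), wt_pct_N=UFloat(0.58, 0.01),
            d15N_mat=UFloat(-5.9, 0.1)),
    }


SITES = {
    "amphitheater_2017": amphitheater_2017,
    "amphitheater_2014": amphitheater_2014,
    "lemonade_creek": lemonade_creek,
    "hot_spring_basin": hot_spring_basin,
}
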