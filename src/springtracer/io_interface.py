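"""Table and config I/O, validation, and report generation.

Water chemistry travels as a long-format CSV (sample_id, analyte, value,
unit[, error]) so that new analytes never force a schema change; vial,
spike, biomass and quench tables are flat CSVs with one row per record.
Values are stored at full precision and rounded only at presentation.
Every run can write a manifest (config hash + seed) beside its outputs so
each number is traceable to its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import DataError
from .uncertainty import UFloat
from .aqueous_speciation import WaterComposition
from .isotope_budget import derive, format_with_error
from .tracer_kinetics import (QuenchCurve, RateInputs,
                              TracerSpike, assimilation_rate,
                              compare_treatments, dissimilation_rate,
                              dpm_from_cpm, light_driven_rate,
                              replicate_mean, total_substrate_mmol)

logger = logging.getLogger("springtracer")

#: unit string -> factor to mol/L
_UNIT_FACTORS = {
    "mol/l": 1.0, "m": 1.0, "mm": 1e-3, "mmol/l": 1e-3,
    "um": 1e-6, "µm": 1e-6, "umol/l": 1e-6, "µmol/l": 1e-6,
    "nm": 1e-9, "nmol/l": 1e-9,
}

#: analyte labels accepted in water tables -> component keys
_ANALYTE_MAP = {
    "fluoride": "F-", "chloride": "Cl-", "bromide": "Br-", "sulfate": "SO4-2",
    "nitrate": "NO3-", "lithium": "Li+", "sodium": "Na+", "potassium": "K+",
    "magnesium": "Mg+2", "calcium": "Ca+2", "ammonium": "NH4+",
    "ferrous iron": "Fe+2", "iron": "Fe+2", "formate": "formate",
    "acetate": "acetate", "dic": "DIC", "sulfide": "sulfide",
    "f-": "F-", "cl-": "Cl-", "br-": "Br-", "so4-2": "SO4-2", "no3-": "NO3-",
    "li+": "Li+", "na+": "Na+", "k+": "K+", "mg+2": "Mg+2", "ca+2": "Ca+2",
    "nh4+": "NH4+", "fe+2": "Fe+2",
}


def _to_mol_per_l(value: float, unit: str, analyte: str) -> float:
    factor = _UNIT_FACTORS.get(unit.strip().lower())
    if factor is None:
        raise DataError(f"malformed unit {unit!r} for analyte {analyte!r}")
    return value * factor


# ---------------------------------------------------------------------------
# water chemistry
# ---------------------------------------------------------------------------

def read_water_table(path: str | Path | io.IOBase) -> dict[str, WaterComposition]:
    """Read a long-format water-chemistry CSV into compositions per sample.

    Required columns: sample_id, analyte, value, unit. ``temperature`` (°C)
    and ``pH`` rows set the sample temperature and field pH; concentration
    rows are unit-normalized to mol/L. Unknown analytes are warned about and
    ignored.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "analyte", "value", "unit"}
    if not required.issubset(df.columns):
        raise DataError(f"water table needs columns {sorted(required)}")
    out: dict[str, WaterComposition] = {}
    for sample_id, grp in df.groupby("sample_id", sort=False):
        temperature = None
        ph = None
        totals: dict[str, float] = {}
        for _, row in grp.iterrows():
            analyte = str(row["analyte"]).strip()
            value = float(row["value"])
            key = analyte.lower()
            if key == "temperature":
                temperature = value
            elif key == "ph":
                ph = value
            elif key in _ANALYTE_MAP:
                comp = _ANALYTE_MAP[key]
                conc = _to_mol_per_l(value, str(row["unit"]), analyte)
                if conc < 0:
                    raise DataError(f"negative concentration for {analyte!r} "
                                    f"in sample {sample_id!r}")
                totals[comp] = conc
            else:
                warnings.warn(f"ignoring unknown analyte {analyte!r} "
                              f"in sample {sample_id!r}", stacklevel=2)
        if temperature is None:
            raise DataError(f"sample {sample_id!r} has no temperature row")
        out[str(sample_id)] = WaterComposition(
            sample_id=str(sample_id), temperature_c=temperature,
            field_pH=ph, totals=totals)
    return out


def write_water_table(compositions: dict[str, WaterComposition],
                      path: str | Path) -> None:
    """Inverse of :func:`read_water_table`; values written in mol/L."""
    rows = []
    for sample_id, comp in compositions.items():
        rows.append({"sample_id": sample_id, "analyte": "temperature",
                     "value": comp.temperature_c, "unit": "C"})
        if comp.field_pH is not None:
            rows.append({"sample_id": sample_id, "analyte": "pH",
                         "value": comp.field_pH, "unit": "pH"})
        for key, tot in comp.totals.items():
            rows.append({"sample_id": sample_id, "analyte": key,
                         "value": repr(tot), "unit": "mol/L"})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# vial / spike / biomass / quench tables
# ---------------------------------------------------------------------------

def read_quench_csv(path: str | Path | io.IOBase) -> QuenchCurve:
    """Columns: quench_indicator, efficiency."""
    df = pd.read_csv(path)
    pts = tuple(sorted((float(q), float(e)) for q, e in
                       zip(df["quench_indicator"], df["efficiency"])))
    return QuenchCurve(pts)


def read_spikes_csv(path: str | Path | io.IOBase) -> dict[str, TracerSpike]:
    """Columns: substrate, activity_uCi, specific_activity_mCi_per_mmol, carbons_per_molecule."""
    df = pd.read_csv(path)
    return {
        str(r["substrate"]): TracerSpike(
            str(r["substrate"]), float(r["activity_uCi"]),
            float(r["specific_activity_mCi_per_mmol"]),
            int(r["carbons_per_molecule"]))
        for _, r in df.iterrows()
    }


def read_biomass_csv(path: str | Path | io.IOBase) -> dict[str, UFloat]:
    """Columns: quantity, value, error (rows gdw, wt_pct_C, optionally wt_pct_N,
    native_concentration_mol_per_l ...)."""
    df = pd.read_csv(path)
    return {str(r["quantity"]): UFloat(float(r["value"]),
                                       float(r.get("error", 0.0) or 0.0))
            for _, r in df.iterrows()}


def read_vials_csv(path: str | Path | io.IOBase) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"vial_id", "substrate", "treatment", "water_volume_ml",
                "slurry_volume_ml", "spike_volume_ml"}
    if not required.issubset(df.columns):
        raise DataError(f"vial table needs columns {sorted(required)}")
    return validate_vial_table(df)


def validate_vial_table(table: pd.DataFrame) -> pd.DataFrame:
    """Enforce vial invariants; warn about missing killed controls.

    Duplicate vial ids are a hard error. When a substrate/treatment design
    lacks killed controls the table still validates, and downstream rate
    computation falls back to a zero killed DPM with a warning flag.
    """
    if table["vial_id"].duplicated().any():
        dupes = table.loc[table["vial_id"].duplicated(), "vial_id"].tolist()
        raise DataError(f"duplicate vial ids: {dupes}")
    vol_cols = [c for c in table.columns if c.endswith("_ml")]
    for c in vol_cols:
        if (table[c].astype(float) < 0).any():
            raise DataError(f"negative volume in column {c!r}")
    for substrate, grp in table.groupby("substrate"):
        if "killed" not in set(grp["treatment"]):
            warnings.warn(f"no killed controls for substrate {substrate!r}; "
                          "rates will be computed against zero DPM",
                          stacklevel=2)
    return table


# ---------------------------------------------------------------------------
# rate pipeline on tables
# ---------------------------------------------------------------------------

def rates_from_tables(vials: pd.DataFrame, spikes: dict[str, TracerSpike],
                      biomass: dict[str, UFloat], quench: QuenchCurve,
                      background_cpm: float = 0.0, t_hours: float = 1.0,
                      F_s_dissimilation: float = 0.25,
                      alpha_level: float = 0.05) -> pd.DataFrame:
    """Per-substrate/assay-mode light, dark and light-driven rates.

    ``biomass`` must provide ``gdw``, ``wt_pct_C`` and per-substrate native
    concentrations under ``native_<substrate>_mol_per_l``.
    """
    vials = validate_vial_table(vials)
    results = []
    for (substrate, assay_mode), grp in vials.groupby(["substrate", "assay_mode"]):
        spike = spikes.get(str(substrate))
        if spike is None:
            raise DataError(f"no spike definition for substrate {substrate!r}")
        native_key = f"native_{substrate}_mol_per_l"
        if native_key not in biomass:
            raise DataError(f"missing {native_key!r} in biomass/constants table")

        def vial_dpm(row) -> float:
            if "dpm" in row and pd.notna(row.get("dpm")):
                return float(row["dpm"])
            return dpm_from_cpm(float(row["cpm"]), background_cpm, quench,
                                float(row.get("quench_indicator", 0.0)))

        dpm_by_treatment = {
            trt: [vial_dpm(r) for _, r in sub.iterrows()]
            for trt, sub in grp.groupby("treatment")
        }
        killed_missing = "killed" not in dpm_by_treatment
        dpm_k = (UFloat(0.0) if killed_missing
                 else replicate_mean(dpm_by_treatment["killed"]))
        native_volume = float(grp["water_volume_ml"].iloc[0]
                              + grp["slurry_volume_ml"].iloc[0])
        mmol = total_substrate_mmol(biomass[native_key], native_volume, spike)
        f_s = 1.0 if assay_mode == "assimilation" else F_s_dissimilation
        common = dict(mmol_substrate=mmol, dpm_added=UFloat(spike.dpm_added),
                      gdw=biomass["gdw"], wt_pct_C=biomass["wt_pct_C"],
                      t_hours=t_hours, F_s=f_s,
                      nu_C=spike.carbons_per_molecule)
        rate_op = (dissimilation_rate if assay_mode == "dissimilation"
                   else assimilation_rate)

        per_treatment = {}
        per_vial = {}
        for trt in ("light", "dark"):
            if trt not in dpm_by_treatment:
                continue
            dpm_t = replicate_mean(dpm_by_treatment[trt])
            per_treatment[trt] = rate_op(RateInputs(dpm_T=dpm_t, dpm_K=dpm_k,
                                                    **common))
            per_vial[trt] = [
                rate_op(RateInputs(dpm_T=UFloat(d), dpm_K=dpm_k, **common)).rate.value
                for d in dpm_by_treatment[trt]]
        for trt, res in per_treatment.items():
            results.append({
                "substrate": substrate, "assay_mode": assay_mode,
                "contrast": trt, "rate": res.rate.value, "error": res.rate.sd,
                "n": len(dpm_by_treatment[trt]), "p_value": float("nan"),
                "distinguishable_from_zero": res.distinguishable_from_zero,
                "killed_missing": killed_missing,
            })
        if "light" in per_treatment and "dark" in per_treatment:
            diff = light_driven_rate(per_treatment["light"], per_treatment["dark"])
            p = float("nan")
            if min(len(per_vial["light"]), len(per_vial["dark"])) >= 2:
                p = compare_treatments(per_vial["light"], per_vial["dark"],
                                       alpha_level).p_value
            results.append({
                "substrate": substrate, "assay_mode": assay_mode,
                "contrast": "light-dark", "rate": diff.rate.value,
                "error": diff.rate.sd,
                "n": len(per_vial["light"]) + len(per_vial["dark"]),
                "p_value": p,
                "distinguishable_from_zero": diff.distinguishable_from_zero,
                "killed_missing": killed_missing,
            })
    return pd.DataFrame(results)


# ---------------------------------------------------------------------------
# run configuration and report
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths, constant overrides and run metadata for a pipeline run."""

    vials: Optional[str] = None
    spikes: Optional[str] = None
    biomass: Optional[str] = None
    quench: Optional[str] = None
    water: Optional[str] = None
    output_dir: str = "."
    seed: int = 0
    alpha_level: float = 0.05
    constants: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return {"config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
                "seed": self.seed}

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2) + "\n")


def render_report(water_results: Optional[dict[str, dict]] = None,
                  rates: Optional[pd.DataFrame] = None) -> str:
    """Plain-text summary: derived water/biomass quantities, then rates.

    ``water_results`` maps sample ids to dicts that may carry
    ``isotopes`` (:class:`IsotopeTable`), ``imbalance_pct``,
    ``balance_pH`` and ``field_pH`` entries. Output is deterministic for
    identical inputs.
    """
    lines = ["# Derived water and biomass quantities", ""]
    for sample_id in sorted(water_results or {}):
        entry = water_results[sample_id]
        lines.append(f"## {sample_id}")
        iso = entry.get("isotopes")
        if iso is not None:
            for name, u in derive(iso).items():
                decimals = 2 if name == "CN_molar" else 1
                lines.append(f"{name}: {format_with_error(u, decimals)}")
        if "field_pH" in entry and entry["field_pH"] is not None:
            lines.append(f"field pH: {entry['field_pH']:.2f}")
        if "balance_pH" in entry:
            lines.append(f"charge-balance pH: {entry['balance_pH']:.2f}")
        if "imbalance_pct" in entry:
            lines.append(f"charge imbalance at field pH: "
                         f"{entry['imbalance_pct']:.1f}%")
        lines.append("")
    lines.append("# Conversion rates, mg C (g C)^-1 h^-1")
    lines.append("")
    if rates is not None and len(rates):
        for _, r in rates.iterrows():
            p = "" if pd.isna(r["p_value"]) else f", p={r['p_value']:.3g}"
            flag = "" if r["distinguishable_from_zero"] else " (not distinguishable from zero)"
            lines.append(f"{r['substrate']} {r['assay_mode']} {r['contrast']}: "
                         f"{r['rate']:.2f} ± {r['error']:.2f} (n={int(r['n'])})"
                         f"{p}{flag}")
    return "\n".join(lines) + "\n"
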