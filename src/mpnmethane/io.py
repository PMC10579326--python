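"""Readers and writers for the pipeline's tab-separated dialects.

Incubation time series arrive as one row per measurement with columns
``station, depth_category, treatment, replicate, time_h`` plus either
``ch4_nmol_headspace`` or ``ch4_ppm`` for the methane amount and either
``atom_pct_13c`` or ``d13C_permil`` for the isotope signal; vessel geometry
and labelling metadata live in a YAML/JSON config keyed by treatment.
Nutrient tables accept ``<LOD`` as a cell value.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .chemistry import DEFAULT_LODS, Censored
from .tracer import (IncubationRecord, IsotopeMeasurement, VesselGeometry,
                     delta13c_to_atom_fraction, ppm_to_nmol)

__all__ = [
    "load_treatment_config",
    "read_incubations",
    "write_incubations",
    "read_nutrient_table",
    "read_count_table",
]

_GEOMETRY_FIELDS = ("liquid_volume", "headspace_volume", "subsample_volume",
                    "temperature", "salinity", "partition_coefficient")


def load_treatment_config(path: str | Path) -> dict:
    """Load the per-treatment geometry/labelling config (YAML or JSON)."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    out = {}
    for treatment, spec in cfg.items():
        geom = {k: spec[k] for k in _GEOMETRY_FIELDS if k in spec}
        out[treatment] = {
            "geometry": VesselGeometry(**geom),
            "labelling_fraction": float(spec.get("labelling_fraction", 1.0)),
        }
    return out


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_incubations(path: str | Path, config: dict) -> list[IncubationRecord]:
    """Read an incubation time-series table into IncubationRecords.

    ``config`` maps treatment -> {"geometry": VesselGeometry,
    "labelling_fraction": float} as produced by
    :func:`load_treatment_config`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    records = []
    keys = ["station", "depth_category", "treatment", "replicate"]
    for (station, depth, treatment, rep), sub in df.groupby(keys, sort=False):
        if treatment not in config:
            raise KeyError(f"no config entry for treatment {treatment!r}")
        geom = config[treatment]["geometry"]
        sub = sub.sort_values("time_h")
        measurements = []
        for _, row in sub.iterrows():
            if "ch4_nmol_headspace" in sub.columns and \
                    pd.notna(row.get("ch4_nmol_headspace")):
                amount = float(row["ch4_nmol_headspace"])
            elif "ch4_ppm" in sub.columns:
                amount = ppm_to_nmol(float(row["ch4_ppm"]),
                                     geom.headspace_volume, geom.temperature)
            else:
                raise ValueError("need ch4_nmol_headspace or ch4_ppm")
            if "atom_pct_13c" in sub.columns and \
                    pd.notna(row.get("atom_pct_13c")):
                x13 = float(row["atom_pct_13c"]) / 100.0
            elif "d13C_permil" in sub.columns:
                x13 = delta13c_to_atom_fraction(float(row["d13C_permil"]))
            else:
                raise ValueError("need atom_pct_13c or d13C_permil")
            measurements.append(IsotopeMeasurement(
                time_h=float(row["time_h"]), ch4_headspace_nmol=amount,
                atom_fraction_13c=x13))
        records.append(IncubationRecord(
            station=str(station), depth_category=str(depth),
            treatment=str(treatment), replicate=str(rep), geometry=geom,
            labelling_fraction=config[treatment]["labelling_fraction"],
            measurements=tuple(measurements)))
    return records


def write_incubations(records, path: str | Path) -> None:
    """Write IncubationRecords in the dialect :func:`read_incubations` reads."""
    path = Path(path)
    rows = []
    for rec in records:
        for m in rec.measurements:
            rows.append((rec.station, rec.depth_category, rec.treatment,
                         rec.replicate, m.time_h, m.ch4_headspace_nmol,
                         m.atom_fraction_13c * 100.0))
    pd.DataFrame(rows, columns=[
        "station", "depth_category", "treatment", "replicate", "time_h",
        "ch4_nmol_headspace", "atom_pct_13c",
    ]).to_csv(path, sep=_sep(path), index=False)


def read_nutrient_table(path: str | Path,
                        lods: dict | None = None) -> pd.DataFrame:
    """Read a nutrient table, mapping ``<LOD`` cells to Censored objects.

    Analyte columns keep numeric values where quantified and
    :class:`~mpnmethane.chemistry.Censored` objects where the cell reads
    ``<LOD`` (case-insensitive, optional number, e.g. ``<10``).
    """
    if lods is None:
        lods = DEFAULT_LODS
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str)

    def convert(col: str, cell):
        if cell is None or (isinstance(cell, float) and pd.isna(cell)) \
                or (isinstance(cell, str) and not cell.strip()):
            return None
        s = str(cell).strip()
        if s.startswith("<"):
            body = s[1:].strip()
            if body.upper() in ("LOD", ""):
                return Censored(lods.get(col, 0.0))
            return Censored(float(body))
        return float(s)

    meta_cols = {"station", "depth_category"}
    out = {}
    for col in df.columns:
        if col in meta_cols:
            out[col] = df[col]
        else:
            out[col] = [convert(col, v) for v in df[col]]
    return pd.DataFrame(out)


def read_count_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep(path))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


__all__.append("write_json")
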