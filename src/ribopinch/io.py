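"""Delimited-table readers and writers for every pipeline stage.

CSV/TSV is the inter-stage lingua franca: each stage consumes and emits a
small documented column schema, inspectable with any spreadsheet.  Time
units may be declared in a leading ``#units: s|min|h`` comment or passed
explicitly; values are converted to seconds on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coupling import ConstructRecord
from .energetics import Condition
from .errors import SchemaError
from .kinetics import TimeCourse, time_unit_factor
from .mg_hill import MgTitration

__all__ = [
    "read_timecourses",
    "read_titration",
    "read_construct_records",
    "construct_records_to_frame",
    "write_json",
]

TIMECOURSE_COLUMNS = ("time", "fraction_intact")
TITRATION_COLUMNS = ("mg_mM", "k_obs_per_s")
RECORD_COLUMNS = ("construct_id", "k_obs_per_s")


def _read_table(path, required: tuple) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:
        raise SchemaError(f"cannot read {path}: {exc}", path=str(path)) from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}",
            path=str(path),
            column=missing[0],
        )
    bad = df[list(required)].isna()
    if bad.any().any():
        row = int(np.argmax(bad.any(axis=1).values))
        col = bad.columns[bad.iloc[row].values.argmax()]
        raise SchemaError(
            f"{path}: missing value in column {col!r} at data row {row}",
            path=str(path), column=str(col), row=row,
        )
    return df


def _declared_unit(path) -> str | None:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.lower().startswith("#units:"):
                return line.split(":", 1)[1].strip()
    return None


def read_timecourses(path, time_unit: str | None = None) -> list:
    """Read fraction-intact time courses, one :class:`TimeCourse` per
    (construct_id, replicate, condition_id) group.

    Columns: ``time``, ``fraction_intact``; optional ``construct_id``,
    ``replicate``, ``condition_id``.  Time unit from ``time_unit`` or a
    ``#units:`` header comment (default seconds).
    """
    unit = time_unit or _declared_unit(path) or "s"
    factor = time_unit_factor(unit)
    df = _read_table(path, TIMECOURSE_COLUMNS)
    for opt in ("construct_id", "replicate", "condition_id"):
        if opt not in df.columns:
            df[opt] = "" if opt != "replicate" else 0
    out = []
    for (cid, rep, cond), grp in df.groupby(
        ["construct_id", "replicate", "condition_id"], sort=False
    ):
        grp = grp.sort_values("time")
        label = f"{cid}" if not rep else f"{cid}:rep{rep}"
        out.append(
            TimeCourse(
                construct_id=str(label),
                times=grp["time"].to_numpy(dtype=float) * factor,
                fraction_intact=grp["fraction_intact"].to_numpy(dtype=float),
                condition_id=str(cond),
            )
        )
    return out


def read_titration(path) -> MgTitration:
    """Read a Mg2+ titration table (columns ``mg_mM``, ``k_obs_per_s``)."""
    df = _read_table(path, TITRATION_COLUMNS)
    df = df.sort_values("mg_mM")
    return MgTitration(
        mg_mM=df["mg_mM"].to_numpy(dtype=float),
        k_obs=df["k_obs_per_s"].to_numpy(dtype=float),
    )


def construct_records_to_frame(records) -> pd.DataFrame:
    """Flatten :class:`ConstructRecord` objects to the panel CSV schema."""
    rows = []
    for r in records:
        rows.append(
            {
                "construct_id": r.construct_id,
                "k_obs_per_s": r.k_obs,
                "stability_kcal": r.stability,
                "p12_bp": r.p12_bp,
                "p12_bits": r.p12_bits,
                "linker_class": r.linker_class,
                "temperature_K": r.condition.temperature,
                "pH": r.condition.pH,
                "monovalent_mM": r.condition.monovalent_mM,
                "mg_mM": r.condition.mg_mM,
                "E_a_kcal": r.E_a_apparent,
                "is_wildtype": r.is_wildtype,
            }
        )
    return pd.DataFrame(rows)


def read_construct_records(path) -> list:
    """Read a construct panel CSV back into :class:`ConstructRecord`s."""
    df = _read_table(path, RECORD_COLUMNS)
    records = []
    for _, row in df.iterrows():
        cond = Condition(
            temperature=float(row.get("temperature_K", 310.15)),
            pH=float(row.get("pH", 7.5)),
            monovalent_mM=float(row.get("monovalent_mM", 150.0)),
            mg_mM=float(row.get("mg_mM", 1.0)),
        )
        def _opt(name, cast=float):
            v = row.get(name)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else cast(v)

        records.append(
            ConstructRecord(
                construct_id=str(row["construct_id"]),
                k_obs=float(row["k_obs_per_s"]),
                stability=_opt("stability_kcal"),
                p12_bp=_opt("p12_bp", int),
                p12_bits=_opt("p12_bits"),
                linker_class=(
                    "" if pd.isna(row.get("linker_class", ""))
                    else str(row.get("linker_class", ""))
                ),
                condition=cond,
                E_a_apparent=_opt("E_a_kcal"),
                is_wildtype=bool(row.get("is_wildtype", False)),
            )
        )
    return records


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
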