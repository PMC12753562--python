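"""The in-memory claims data model and its delimited-text serialization.

A :class:`ClaimsDataset` bundles five tables (patients, diagnoses,
prescriptions, hospitalizations, measurements).  In memory every date column
holds integer day offsets from :data:`tmcohort.dates.EPOCH`; on disk the
tables are UTF-8 CSV files with a header row and ISO-8601 dates, one file
per table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .dates import dates_to_days, days_to_dates

PATIENT_COLUMNS = ["patient_id", "sex", "birth_date", "observable_start", "observable_end"]
DIAGNOSIS_COLUMNS = ["patient_id", "date", "code", "facility_id", "setting", "hospitalization_id"]
PRESCRIPTION_COLUMNS = [
    "patient_id",
    "date",
    "code",
    "days_supply",
    "daily_dose",
    "facility_id",
    "setting",
    "hospitalization_id",
]
HOSPITALIZATION_COLUMNS = ["hospitalization_id", "patient_id", "admission_date", "discharge_date"]
MEASUREMENT_COLUMNS = ["patient_id", "date", "kind", "value"]

_DATE_COLUMNS = {
    "patients": ["birth_date", "observable_start", "observable_end"],
    "diagnoses": ["date"],
    "prescriptions": ["date"],
    "hospitalizations": ["admission_date", "discharge_date"],
    "measurements": ["date"],
}
_SCHEMA = {
    "patients": PATIENT_COLUMNS,
    "diagnoses": DIAGNOSIS_COLUMNS,
    "prescriptions": PRESCRIPTION_COLUMNS,
    "hospitalizations": HOSPITALIZATION_COLUMNS,
    "measurements": MEASUREMENT_COLUMNS,
}


class SchemaError(ValueError):
    """A claims table does not match the documented schema."""


def _empty(table: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype="object") for c in _SCHEMA[table]})


@dataclass
class ClaimsDataset:
    """Five claims tables; the universe cohorts are built from."""

    patients: pd.DataFrame = field(default_factory=lambda: _empty("patients"))
    diagnoses: pd.DataFrame = field(default_factory=lambda: _empty("diagnoses"))
    prescriptions: pd.DataFrame = field(default_factory=lambda: _empty("prescriptions"))
    hospitalizations: pd.DataFrame = field(default_factory=lambda: _empty("hospitalizations"))
    measurements: pd.DataFrame = field(default_factory=lambda: _empty("measurements"))

    def tables(self):
        for f in fields(self):
            yield f.name, getattr(self, f.name)

    def equals(self, other: "ClaimsDataset") -> bool:
        for (name, mine), (_, theirs) in zip(self.tables(), other.tables()):
            a = mine.reset_index(drop=True)
            b = theirs.reset_index(drop=True)
            if len(a) != len(b) or list(a.columns) != list(b.columns):
                return False
            if len(a) and not a.sort_values(list(a.columns)).reset_index(drop=True).equals(
                b.sort_values(list(b.columns)).reset_index(drop=True)
            ):
                return False
        return True


def validate(dataset: ClaimsDataset) -> None:
    """Check dataset-level invariants; raise SchemaError on violation."""
    for name, table in dataset.tables():
        missing = [c for c in _SCHEMA[name] if c not in table.columns]
        if missing:
            raise SchemaError(f"table '{name}' is missing column(s): {', '.join(missing)}")
    rx = dataset.prescriptions
    if len(rx) and (rx["days_supply"].astype(float) < 1).any():
        bad = int(np.argmax(rx["days_supply"].astype(float).to_numpy() < 1))
        raise SchemaError(f"table 'prescriptions' row {bad}: days_supply < 1")

    pat = dataset.patients.set_index("patient_id")
    for name in ("diagnoses", "prescriptions", "measurements"):
        table = getattr(dataset, name)
        if not len(table):
            continue
        start = pat["observable_start"].reindex(table["patient_id"]).to_numpy()
        end = pat["observable_end"].reindex(table["patient_id"]).to_numpy()
        day = table["date"].to_numpy()
        bad = (day < start) | (day > end)
        if bad.any():
            row = int(np.argmax(bad))
            raise SchemaError(
                f"table '{name}' row {row}: date outside the patient's observable period"
            )

    hosp = dataset.hospitalizations
    if len(hosp):
        hosp_idx = hosp.set_index("hospitalization_id")
        for name in ("diagnoses", "prescriptions"):
            table = getattr(dataset, name)
            if not len(table):
                continue
            hid = table["hospitalization_id"]
            linked = table[hid.notna()]
            if not len(linked):
                continue
            adm = hosp_idx["admission_date"].reindex(linked["hospitalization_id"]).to_numpy()
            dis = hosp_idx["discharge_date"].reindex(linked["hospitalization_id"]).to_numpy()
            hpid = hosp_idx["patient_id"].reindex(linked["hospitalization_id"]).to_numpy()
            day = linked["date"].to_numpy()
            bad = (
                np.isnan(adm.astype(float))
                | (hpid != linked["patient_id"].to_numpy())
                | (day < adm)
                | (day > dis)
            )
            if bad.any():
                row = int(linked.index[np.argmax(bad)])
                raise SchemaError(
                    f"table '{name}' row {row}: hospitalization_id does not resolve to a "
                    "same-patient hospitalization containing the record date"
                )


def write_claims(dataset: ClaimsDataset, directory) -> list[Path]:
    """Write the five tables as CSV files; returns the file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in dataset.tables():
        out = table.copy()
        for col in _DATE_COLUMNS[name]:
            if len(out):
                out[col] = days_to_dates(out[col]).to_numpy()
        path = directory / f"{name}.csv"
        out.to_csv(path, index=False)
        written.append(path)
    return written


def read_claims(directory) -> ClaimsDataset:
    """Read a dataset previously written by :func:`write_claims`.

    Malformed tables raise :class:`SchemaError` naming the table, column and
    (for unparseable dates) the offending row.
    """
    directory = Path(directory)
    loaded = {}
    for name, columns in _SCHEMA.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"table '{name}': file {path} not found")
        table = pd.read_csv(path)
        if not len(table) and not len(table.columns):
            table = _empty(name)
        missing = [c for c in columns if c not in table.columns]
        if missing:
            raise SchemaError(f"table '{name}' is missing column(s): {', '.join(missing)}")
        for col in _DATE_COLUMNS[name]:
            if not len(table):
                table[col] = pd.Series(dtype="int64")
                continue
            try:
                table[col] = dates_to_days(table[col])
            except (ValueError, TypeError):
                parsed = pd.to_datetime(table[col], format="ISO8601", errors="coerce")
                row = int(np.argmax(parsed.isna().to_numpy()))
                raise SchemaError(
                    f"table '{name}' row {row}: unparseable date in column '{col}'"
                ) from None
        if name in ("diagnoses", "prescriptions"):
            table["hospitalization_id"] = table["hospitalization_id"].astype("Int64")
        loaded[name] = table
    return ClaimsDataset(**loaded)
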