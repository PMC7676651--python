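"""Reading, writing and validation of the two cohort tables.

``counts.csv``   — patient_id,population,timepoint,count
``patients.csv`` — patient_id,ne_dose,group,euroscore2,<covariates...>

Both files are comma-separated UTF-8 with a mandatory header and "."
decimals.  Count tables are normalized to a canonical row order (patient,
then population and time point in schema order) so that write∘read is the
identity on validated tables and equal tables serialize to equal bytes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ValidationError
from .schema import BASELINES, NE_CUTOFF_MG_PER_KG, POPULATIONS, TIMEPOINTS

__all__ = [
    "PatientRecord",
    "read_count_table",
    "write_count_table",
    "validate_count_table",
    "read_patient_table",
    "write_patient_table",
    "records_from_frame",
]

_COUNT_COLUMNS = ["patient_id", "population", "timepoint", "count"]
_PATIENT_CORE = ["patient_id", "ne_dose", "group", "euroscore2"]


@dataclass
class PatientRecord:
    """One enrolled patient: identity, NE dose, group, risk, covariates."""

    patient_id: str
    ne_dose: float
    group: str | None = None  # "G1" | "G2" | None (unassigned)
    euroscore2: float | None = None
    covariates: dict[str, object] = field(default_factory=dict)


def _fmt(value: object) -> str:
    """Canonical CSV cell: integral floats print without decimals."""
    if isinstance(value, float):
        if value != value:  # NaN -> empty cell
            return ""
        if value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return repr(value)
    if value is None:
        return ""
    return str(value)


def validate_count_table(df: pd.DataFrame, allow_missing: bool = False) -> pd.DataFrame:
    """Validate and canonically order a count table.

    Checks the closed population/time-point vocabularies, non-negative
    counts and uniqueness of (patient_id, population, timepoint).  Error
    messages name the offending row (0-based data row) and field.
    """
    missing_cols = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"count table missing column(s): {', '.join(missing_cols)}")
    df = df[_COUNT_COLUMNS].copy()
    df["patient_id"] = df["patient_id"].astype(str)

    for row, pop in enumerate(df["population"]):
        if pop not in POPULATIONS:
            raise ValidationError(f"row {row}: unknown population {pop!r}")
    for row, tp in enumerate(df["timepoint"]):
        if tp not in TIMEPOINTS:
            raise ValidationError(f"row {row}: unknown timepoint {tp!r}")

    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() & df["count"].notna() & (df["count"].astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax())
        raise ValidationError(
            f"row {row}: non-numeric count {df['count'].iloc[row]!r}"
        )
    df["count"] = counts
    if df["count"].isna().any():
        if not allow_missing:
            row = int(df["count"].isna().idxmax())
            raise ValidationError(f"row {row}: missing count (allow_missing=False)")
    if (df["count"] < 0).any():
        row = int((df["count"] < 0).idxmax())
        raise ValidationError(f"row {row}: negative count {df['count'].iloc[row]}")

    dup = df.duplicated(subset=["patient_id", "population", "timepoint"])
    if dup.any():
        row = int(dup.idxmax())
        key = tuple(df.loc[row, ["patient_id", "population", "timepoint"]])
        raise ValidationError(f"row {row}: duplicate key {key}")

    df["population"] = pd.Categorical(df["population"], categories=POPULATIONS, ordered=True)
    df["timepoint"] = pd.Categorical(df["timepoint"], categories=TIMEPOINTS, ordered=True)
    df = df.sort_values(_COUNT_COLUMNS[:3], kind="stable").reset_index(drop=True)
    df["population"] = df["population"].astype(str)
    df["timepoint"] = df["timepoint"].astype(str)
    df["count"] = df["count"].astype(float)
    return df


def read_count_table(path: str | Path, allow_missing: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    return validate_count_table(df, allow_missing=allow_missing)


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    df = validate_count_table(df, allow_missing=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COUNT_COLUMNS)
        for row in df.itertuples(index=False):
            writer.writerow([_fmt(v) for v in row])


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    """Read patients.csv into records; the group column is optional."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    for col in ("patient_id", "ne_dose"):
        if col not in df.columns:
            raise ValidationError(f"patient table missing column: {col}")
    dup = df["patient_id"].astype(str).duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate patient_id {df['patient_id'][dup].iloc[0]!r}"
        )
    records: list[PatientRecord] = []
    covariate_cols = [c for c in df.columns if c not in _PATIENT_CORE]
    for row, rec in enumerate(df.to_dict("records")):
        try:
            ne_dose = float(rec["ne_dose"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"row {row}: non-numeric ne_dose {rec['ne_dose']!r}"
            ) from None
        if ne_dose < 0:
            raise ValidationError(f"row {row}: negative ne_dose {ne_dose}")
        group = rec.get("group")
        if group is not None and (pd.isna(group) or group == ""):
            group = None
        if group is not None:
            if group not in ("G1", "G2"):
                raise ValidationError(f"row {row}: unknown group {group!r}")
            expected = "G1" if ne_dose <= NE_CUTOFF_MG_PER_KG else "G2"
            if group != expected:
                raise ValidationError(
                    f"row {row}: group {group} inconsistent with ne_dose "
                    f"{ne_dose} under the {NE_CUTOFF_MG_PER_KG} mg/kg rule"
                )
        euroscore2 = rec.get("euroscore2")
        if euroscore2 is not None and pd.isna(euroscore2):
            euroscore2 = None
        if euroscore2 is not None:
            euroscore2 = float(euroscore2)
            if euroscore2 < 0:
                raise ValidationError(f"row {row}: negative euroscore2 {euroscore2}")
        covariates = {c: rec[c] for c in covariate_cols if not pd.isna(rec.get(c))}
        records.append(
            PatientRecord(
                patient_id=str(rec["patient_id"]),
                ne_dose=ne_dose,
                group=group,
                euroscore2=euroscore2,
                covariates=covariates,
            )
        )
    return records


def write_patient_table(
    patients: pd.DataFrame | Iterable[PatientRecord], path: str | Path
) -> None:
    if not isinstance(patients, pd.DataFrame):
        rows = []
        for rec in patients:
            row = {
                "patient_id": rec.patient_id,
                "ne_dose": rec.ne_dose,
                "group": rec.group,
                "euroscore2": rec.euroscore2,
            }
            row.update(rec.covariates)
            rows.append(row)
        patients = pd.DataFrame(rows)
    cols = [c for c in _PATIENT_CORE if c in patients.columns]
    cols += [c for c in patients.columns if c not in cols]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for row in patients[cols].itertuples(index=False):
            writer.writerow([_fmt(v) for v in row])


def group_map(patients: pd.DataFrame | Iterable[PatientRecord]) -> dict[str, str]:
    """patient_id -> assigned group; unassigned patients are omitted."""
    if isinstance(patients, pd.DataFrame):
        patients = records_from_frame(patients)
    return {p.patient_id: p.group for p in patients if p.group is not None}


def baseline_for(name: str) -> str:
    """Map a baseline label (B1/B2/P0) to its time point."""
    try:
        return BASELINES[name]
    except KeyError:
        raise ValidationError(
            f"unknown baseline {name!r}; expected one of {sorted(BASELINES)}"
        ) from None
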