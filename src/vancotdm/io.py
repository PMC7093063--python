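"""CSV readers and writers for patient covariates and trough observations.

Schemas (exact header names):

* patients:  ``patient_id, age_years, sex, black_race, scr_mg_dl,
  weight_kg, renal_modality`` with sex in {M, F}, black_race in {0, 1},
  renal_modality in {none, ihd, crrt, unstable};
* troughs:   ``patient_id, group, trough_mcg_ml, weight_kg, egfr`` with
  weight_kg / egfr optional (blank) per row, plus an optional ``modality``
  column.

Validation is row-by-row: every malformed row is collected and reported
with its line number and offending column, rather than failing on the
first error.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .evaluation import TroughObservation
from .renal import PatientCovariates, RenalModality, Sex

__all__ = [
    "SchemaError",
    "PATIENT_COLUMNS",
    "TROUGH_COLUMNS",
    "read_patients",
    "write_patients",
    "read_troughs",
    "write_troughs",
]

PATIENT_COLUMNS = [
    "patient_id",
    "age_years",
    "sex",
    "black_race",
    "scr_mg_dl",
    "weight_kg",
    "renal_modality",
]
TROUGH_COLUMNS = ["patient_id", "group", "trough_mcg_ml", "weight_kg", "egfr"]

_SEX = {"M": Sex.MALE, "F": Sex.FEMALE}
_MODALITY = {m.value: m for m in RenalModality}


class SchemaError(ValueError):
    """One or more rows (or the header) violated the CSV schema."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def _check_header(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError([f"{path}: missing column(s) {', '.join(missing)}"])


def read_patients(path: str | Path) -> list[PatientCovariates]:
    """Read and validate a patient covariate CSV."""
    df = pd.read_csv(path, dtype=str).fillna("")
    _check_header(df, PATIENT_COLUMNS, path)
    patients: list[PatientCovariates] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            sex = _SEX.get(row["sex"].strip())
            if sex is None:
                raise ValueError(f"column 'sex': {row['sex']!r} not in {{M,F}}")
            race = row["black_race"].strip()
            if race not in ("0", "1"):
                raise ValueError(f"column 'black_race': {race!r} not in {{0,1}}")
            modality = _MODALITY.get(row["renal_modality"].strip())
            if modality is None:
                raise ValueError(
                    f"column 'renal_modality': {row['renal_modality']!r} "
                    "not in {none,ihd,crrt,unstable}"
                )
            try:
                age = float(row["age_years"])
                scr = float(row["scr_mg_dl"])
                weight = float(row["weight_kg"])
            except ValueError as exc:
                raise ValueError(f"unparseable numeric value ({exc})") from None
            patients.append(
                PatientCovariates(
                    age_years=age,
                    sex=sex,
                    black_race=race == "1",
                    scr_mg_dl=scr,
                    weight_kg=weight,
                    modality=modality,
                )
            )
        except ValueError as exc:
            errors.append(f"{path} line {line}: {exc}")
    if errors:
        raise SchemaError(errors)
    return patients


def write_patients(
    patients: Sequence[PatientCovariates],
    path: str | Path,
    ids: Sequence[str] | None = None,
) -> None:
    rows = []
    for i, p in enumerate(patients):
        rows.append(
            {
                "patient_id": ids[i] if ids is not None else f"P{i:05d}",
                "age_years": p.age_years,
                "sex": "M" if p.sex is Sex.MALE else "F",
                "black_race": int(p.black_race),
                "scr_mg_dl": p.scr_mg_dl,
                "weight_kg": p.weight_kg,
                "renal_modality": p.modality.value,
            }
        )
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, index=False)


def read_troughs(path: str | Path) -> list[TroughObservation]:
    """Read a trough-observation CSV (weight/eGFR may be blank per row)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    _check_header(df, TROUGH_COLUMNS, path)
    obs: list[TroughObservation] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            try:
                conc = float(row["trough_mcg_ml"])
            except ValueError:
                raise ValueError(
                    f"column 'trough_mcg_ml': unparseable {row['trough_mcg_ml']!r}"
                ) from None
            group = row["group"].strip()
            if not group:
                raise ValueError("column 'group': empty label")
            weight = float(row["weight_kg"]) if row["weight_kg"].strip() else None
            egfr = float(row["egfr"]) if row["egfr"].strip() else None
            modality = RenalModality.NONE
            if "modality" in df.columns and row["modality"].strip():
                m = _MODALITY.get(row["modality"].strip())
                if m is None:
                    raise ValueError(f"column 'modality': {row['modality']!r}")
                modality = m
            obs.append(
                TroughObservation(
                    concentration=conc,
                    group=group,
                    weight_kg=weight,
                    egfr=egfr,
                    modality=modality,
                )
            )
        except ValueError as exc:
            errors.append(f"{path} line {line}: {exc}")
    if errors:
        raise SchemaError(errors)
    return obs


def write_troughs(df_or_obs, path: str | Path) -> None:
    """Write trough observations (a tidy DataFrame or observation list)."""
    if isinstance(df_or_obs, pd.DataFrame):
        df_or_obs.to_csv(path, index=False)
        return
    rows = []
    for i, o in enumerate(df_or_obs):
        rows.append(
            {
                "patient_id": f"P{i:05d}",
                "group": o.group,
                "trough_mcg_ml": o.concentration,
                "weight_kg": "" if o.weight_kg is None else o.weight_kg,
                "egfr": "" if o.egfr is None else o.egfr,
            }
        )
    pd.DataFrame(rows, columns=TROUGH_COLUMNS).to_csv(path, index=False)
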