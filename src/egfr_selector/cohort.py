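"""Cohort table contract: CSV layout and conversion to patient records.

The on-disk format is a plain CSV with one row per patient.  Column names
match :class:`~egfr_selector.equations.PatientRecord` field names, ``sex``
is coded ``male``/``female``, boolean covariates are ``0``/``1``, missing
values are empty cells, and ``scr_unit`` is ``mg/dL`` or ``umol/L``
(defaulting to ``umol/L`` when the column is absent).
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .equations import (
    PatientRecord,
    body_mass_index,
    convert_creatinine,
    du_bois_bsa,
    normalize_gfr,
)

__all__ = [
    "BOOLEAN_COVARIATES",
    "CATEGORY_COVARIATES",
    "NUMERIC_COVARIATES",
    "COVARIATE_COLUMNS",
    "CORE_COLUMNS",
    "COHORT_COLUMNS",
    "DEFAULT_TREE_COVARIATES",
    "read_cohort",
    "write_cohort",
    "add_derived_columns",
    "frame_to_records",
    "records_to_frame",
]

BOOLEAN_COVARIATES: Sequence[str] = (
    "diabetic_nephropathy",
    "rasi",
    "diabetes",
    "smoking",
    "drinking",
    "unilateral_nephrectomy",
    "edema",
    "gout",
    "hyperuricemia",
    "cardiovascular_disease",
    "cerebral_infarction",
    "cerebral_hemorrhage",
    "cancer",
    "calcium_dobesilate",
    "sglt2i",
    "beraprost",
    "glucocorticoid",
    "immunosuppressor",
    "diuretic",
)

CATEGORY_COVARIATES: Sequence[str] = ("hypertension_grade", "renal_pathology")

NUMERIC_COVARIATES: Sequence[str] = ("urine_protein_24h", "urine_volume_24h")

COVARIATE_COLUMNS: Sequence[str] = (
    tuple(BOOLEAN_COVARIATES) + tuple(CATEGORY_COVARIATES) + tuple(NUMERIC_COVARIATES)
)

CORE_COLUMNS: Sequence[str] = (
    "patient_id",
    "age",
    "sex",
    "height",
    "weight",
    "scr",
    "scr_unit",
    "cysc",
    "bun",
    "alb",
    "sgfr_abs",
)

COHORT_COLUMNS: Sequence[str] = tuple(CORE_COLUMNS) + tuple(COVARIATE_COLUMNS)

#: The covariates offered to the selector tree by default: demographics,
#: body habitus (derived BSA/BMI), history/medication flags, renal pathology
#: (plus its binarized diabetic-nephropathy indicator), creatinine (umol/L),
#: cystatin C and the 24-h urine measurements.
DEFAULT_TREE_COVARIATES: Sequence[str] = (
    "age",
    "sex",
    "bsa",
    "bmi",
    "diabetic_nephropathy",
    "unilateral_nephrectomy",
    "hypertension_grade",
    "diabetes",
    "cardiovascular_disease",
    "cerebral_infarction",
    "cerebral_hemorrhage",
    "cancer",
    "hyperuricemia",
    "gout",
    "edema",
    "calcium_dobesilate",
    "sglt2i",
    "rasi",
    "beraprost",
    "glucocorticoid",
    "immunosuppressor",
    "diuretic",
    "smoking",
    "drinking",
    "renal_pathology",
    "scr_umol",
    "cysc",
    "urine_volume_24h",
    "urine_protein_24h",
)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, normalizing dtypes per the column contract."""
    frame = pd.read_csv(path, dtype={"patient_id": str})
    if "scr_unit" not in frame.columns:
        frame["scr_unit"] = "umol/L"
    frame["scr_unit"] = frame["scr_unit"].fillna("umol/L")
    for col in BOOLEAN_COVARIATES:
        if col in frame.columns:
            frame[col] = frame[col].fillna(0).astype(int)
    for col in CATEGORY_COVARIATES:
        if col in frame.columns:
            frame[col] = frame[col].fillna("none").astype(str)
    return frame


def write_cohort(frame: pd.DataFrame, path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in cols]
    frame[cols + extra].to_csv(path, index=False)


def add_derived_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``bsa``, ``bmi``, ``scr_umol`` and (when measured
    GFR is present) ``sgfr_norm`` columns appended."""
    out = frame.copy()
    out["bsa"] = [
        du_bois_bsa(w, h) for w, h in zip(out["weight"], out["height"])
    ]
    out["bmi"] = [
        body_mass_index(w, h) for w, h in zip(out["weight"], out["height"])
    ]
    out["scr_umol"] = [
        convert_creatinine(v, u, "umol/L")
        for v, u in zip(out["scr"], out["scr_unit"])
    ]
    if "sgfr_abs" in out.columns and out["sgfr_abs"].notna().any():
        out["sgfr_norm"] = [
            normalize_gfr(g, b) if pd.notna(g) else np.nan
            for g, b in zip(out["sgfr_abs"], out["bsa"])
        ]
    return out


def _opt(value) -> Optional[float]:
    return None if pd.isna(value) else float(value)


def frame_to_records(frame: pd.DataFrame) -> List[PatientRecord]:
    records = []
    for _, row in frame.iterrows():
        covariates = {
            col: row[col] for col in COVARIATE_COLUMNS if col in frame.columns
        }
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                age=float(row["age"]),
                sex=row["sex"],
                height=float(row["height"]),
                weight=float(row["weight"]),
                scr=float(row["scr"]),
                scr_unit=str(row.get("scr_unit", "umol/L")),
                cysc=_opt(row.get("cysc")),
                bun=_opt(row.get("bun")),
                alb=_opt(row.get("alb")),
                sgfr_abs=_opt(row.get("sgfr_abs")),
                covariates=covariates,
            )
        )
    return records


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "patient_id": rec.patient_id,
            "age": rec.age,
            "sex": rec.sex.value,
            "height": rec.height,
            "weight": rec.weight,
            "scr": rec.scr,
            "scr_unit": rec.scr_unit,
            "cysc": rec.cysc,
            "bun": rec.bun,
            "alb": rec.alb,
            "sgfr_abs": rec.sgfr_abs,
        }
        row.update(rec.covariates)
        rows.append(row)
    frame = pd.DataFrame(rows)
    ordered = [c for c in COHORT_COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in ordered]
    return frame[ordered + extra]


def record_covariate_row(record: PatientRecord) -> dict:
    """Covariate mapping (incl. derived bsa/bmi/scr_umol) used for tree
    routing of a single record."""
    row = {
        "age": record.age,
        "sex": record.sex.value,
        "bsa": record.bsa,
        "bmi": record.bmi,
        "scr_umol": record.scr_umoll,
        "cysc": record.cysc,
    }
    row.update(record.covariates)
    return row


__all__.append("record_covariate_row")
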