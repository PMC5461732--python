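"""CSV schemas, boolean parsing and report rendering.

Patient files are comma-separated UTF-8 with a mandatory header. The flag
columns use short report names (``chf``, ``cvd``, ...) mapped onto the
descriptive field names of :class:`~practice_futi.score.PatientPresentation`;
when a flag column is absent but the matching raw-vitals column (``rr``,
``sbp``, ``pulse``, ``temp``) is present, the measurement is dichotomized at
the table cut-off.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import DataCompletenessError, PracticeError
from .evaluation import round_half_up
from .score import (
    PULSE_CUTOFF,
    RESPIRATORY_RATE_CUTOFF,
    SYSTOLIC_BP_CUTOFF,
    TEMPERATURE_CUTOFF,
    FLAG_FIELDS,
    PatientPresentation,
)

__all__ = [
    "PATIENT_FLAG_COLUMNS",
    "read_patients_frame",
    "read_patients",
    "read_outcomes",
    "format_count_pct",
    "render_report",
]

PathLike = Union[str, Path]

#: CSV column name -> PatientPresentation field name, in schema order.
PATIENT_FLAG_COLUMNS: dict[str, str] = {
    "nursing_home": "nursing_home_resident",
    "malignancy": "malignancy",
    "chf": "congestive_heart_failure",
    "cvd": "cerebrovascular_disease",
    "cirrhosis": "liver_cirrhosis",
    "renal_disease": "renal_disease",
    "altered_mental_status": "altered_mental_status",
    "rr_ge_30": "respiratory_rate_ge_30",
    "sbp_lt_90": "systolic_bp_lt_90",
    "pulse_ge_125": "pulse_ge_125",
    "temp_ge_40": "temperature_ge_40",
}

#: Raw-vitals fallback: CSV column -> (flag column, dichotomization).
_VITALS_FALLBACK = {
    "rr_ge_30": ("rr", lambda v: v >= RESPIRATORY_RATE_CUTOFF),
    "sbp_lt_90": ("sbp", lambda v: v < SYSTOLIC_BP_CUTOFF),
    "pulse_ge_125": ("pulse", lambda v: v >= PULSE_CUTOFF),
    "temp_ge_40": ("temp", lambda v: v >= TEMPERATURE_CUTOFF),
}

_OUTCOME_COLUMNS = (
    "patient_id",
    "admitted",
    "secondary_admission",
    "icu",
    "death30",
    "death90",
    "hosp_days",
    "afebrile_fu",
    "sev_base",
    "sev_fu",
    "relapse_rx",
    "fu_cfu",
    "fu_leuco",
)

_TRUE_STRINGS = {"1", "true", "t", "yes", "y"}
_FALSE_STRINGS = {"0", "false", "f", "no", "n"}


def _parse_bool_column(series: pd.Series, column: str) -> pd.Series:
    """Parse 0/1 and case-insensitive true/false; report the first bad row."""
    out = np.empty(len(series), dtype=bool)
    for pos, value in enumerate(series):
        if isinstance(value, (bool, np.bool_)):
            out[pos] = bool(value)
            continue
        if isinstance(value, (int, np.integer, float, np.floating)) and value in (0, 1):
            out[pos] = bool(value)
            continue
        text = str(value).strip().lower()
        if text in _TRUE_STRINGS:
            out[pos] = True
        elif text in _FALSE_STRINGS:
            out[pos] = False
        else:
            raise PracticeError(
                f"cannot parse {value!r} in column {column!r} as a boolean "
                f"(data row {pos + 1})"
            )
    return pd.Series(out, index=series.index)


def read_patients_frame(path: PathLike) -> pd.DataFrame:
    """Read a patient CSV into a normalized frame.

    Returns columns ``patient_id``, ``age``, ``sex`` and the eleven flag
    fields under their descriptive names, preserving row order. Unknown
    columns raise a warning; missing required columns raise
    :class:`DataCompletenessError` listing every absent field; an
    unparseable value raises an error naming its row.
    """
    raw = pd.read_csv(path)
    raw.columns = [c.strip() for c in raw.columns]
    known = {"patient_id", "age", "sex", *PATIENT_FLAG_COLUMNS, "rr", "sbp", "pulse", "temp"}
    unknown = [c for c in raw.columns if c not in known]
    if unknown:
        warnings.warn(f"ignoring unknown column(s): {unknown}", stacklevel=2)

    missing = [c for c in ("patient_id", "age", "sex") if c not in raw.columns]
    for csv_col, (vital_col, _) in _VITALS_FALLBACK.items():
        if csv_col not in raw.columns and vital_col not in raw.columns:
            missing.append(csv_col)
    missing.extend(
        c
        for c in PATIENT_FLAG_COLUMNS
        if c not in raw.columns and c not in _VITALS_FALLBACK
    )
    if missing:
        raise DataCompletenessError(missing, f"input is missing column(s): {missing}")

    out = pd.DataFrame(index=raw.index)
    out["patient_id"] = raw["patient_id"]
    ages = pd.to_numeric(raw["age"], errors="coerce")
    if ages.isna().any():
        row = int(ages.index[ages.isna()][0]) + 1
        raise PracticeError(f"cannot parse age (data row {row})")
    out["age"] = ages
    out["sex"] = raw["sex"].astype(str).str.strip().str.upper()
    for csv_col, field_name in PATIENT_FLAG_COLUMNS.items():
        if csv_col in raw.columns:
            out[field_name] = _parse_bool_column(raw[csv_col], csv_col)
        else:
            vital_col, rule = _VITALS_FALLBACK[csv_col]
            values = pd.to_numeric(raw[vital_col], errors="coerce")
            if values.isna().any():
                row = int(values.index[values.isna()][0]) + 1
                raise PracticeError(
                    f"cannot parse {vital_col!r} (data row {row})"
                )
            out[field_name] = rule(values)
    return out


def read_patients(path: PathLike) -> list[tuple[object, PatientPresentation]]:
    """Read a patient CSV into ``(patient_id, PatientPresentation)`` pairs."""
    frame = read_patients_frame(path)
    patients = []
    for _, row in frame.iterrows():
        flags = {name: bool(row[name]) for name in FLAG_FIELDS}
        patients.append(
            (row["patient_id"], PatientPresentation(age=row["age"], sex=row["sex"], **flags))
        )
    return patients


def read_outcomes(path: PathLike) -> pd.DataFrame:
    """Read an outcome CSV (schema: patient_id, admitted, secondary_admission,
    icu, death30, death90, hosp_days, afebrile_fu, sev_base, sev_fu,
    relapse_rx, fu_cfu, fu_leuco). Optional columns may be absent; empty
    cells in culture fields stay missing (not evaluable)."""
    raw = pd.read_csv(path)
    raw.columns = [c.strip() for c in raw.columns]
    if "patient_id" not in raw.columns:
        raise DataCompletenessError("patient_id")
    unknown = [c for c in raw.columns if c not in _OUTCOME_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown column(s): {unknown}", stacklevel=2)
    out = raw[[c for c in _OUTCOME_COLUMNS if c in raw.columns]].copy()
    for col in ("admitted", "secondary_admission", "icu", "death30", "death90",
                "afebrile_fu", "relapse_rx"):
        if col in out.columns:
            out[col] = _parse_bool_column(out[col], col)
    return out


def format_count_pct(count: int, denominator: int) -> str:
    """Render ``count (percent)`` in the report style, e.g. ``219 (92)``.

    Percentages are rounded half-up to whole points; a zero denominator
    renders as ``count (-)``.
    """
    if denominator <= 0:
        return f"{count} (-)"
    return f"{count} ({round_half_up(100.0 * count / denominator)})"


def render_report(table: pd.DataFrame) -> pd.DataFrame:
    """Render a per-class outcome table with counts as ``n (%)`` strings.

    Deterministic column order: risk class, n, then each event as a single
    ``n (%)`` column, then the length-of-stay median [IQR].
    """
    if table.empty:
        return pd.DataFrame(columns=["risk_class", "n"])
    out = pd.DataFrame()
    out["risk_class"] = table["risk_class"]
    out["n"] = table["n"].astype(int)
    for col in ("death30", "death90", "icu"):
        if f"{col}_n" in table.columns:
            out[col] = [
                format_count_pct(int(k), int(n))
                for k, n in zip(table[f"{col}_n"], table["n"])
            ]
    if "los_median" in table.columns:
        out["los_median_iqr"] = [
            "-" if pd.isna(m) else f"{m:g} [{i:g}]"
            for m, i in zip(table["los_median"], table["los_iqr"])
        ]
    return out
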