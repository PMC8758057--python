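"""Reading and writing the cohort, label and treatment tables.

The cohort table is RFC-4180 CSV with one row per subject: ``subject_id``,
optional ``age`` and ``group_label`` (case/control), then one column per
battery item.  Validation reports offending row numbers (1-based data
rows) and item names.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .instruments import battery, item_ids
from .simulate import TreatmentRecord

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "read_labels_csv",
    "write_labels_csv",
    "read_treatment_csv",
    "write_treatment_csv",
]

log = logging.getLogger("bladderpheno")

OPTIONAL_COLUMNS = ("age", "group_label")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort table; errors name rows and items."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"cohort file not found: {path}")
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValidationError("cohort table must have a subject_id column")
    batt = battery()
    unknown = [c for c in df.columns
               if c not in batt and c != "subject_id" and c not in OPTIONAL_COLUMNS]
    if unknown:
        raise ValidationError(f"unknown column(s): {', '.join(unknown)}")
    missing = [c for c in item_ids() if c not in df.columns]
    if missing:
        raise ValidationError(f"missing item column(s): {', '.join(missing)}")
    if df.empty:
        log.warning("cohort file %s has a header but no rows", path)
        return df
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate subject_id(s): {', '.join(map(str, dup.unique()))}")
    for col, d in batt.items():
        bad = df.index[(df[col] < d.scale_min) | (df[col] > d.scale_max) | df[col].isna()]
        if len(bad):
            row = int(bad[0]) + 1
            raise ValidationError(
                f"row {row}, item {col}: value {df.loc[bad[0], col]!r} outside "
                f"scale [{d.scale_min}, {d.scale_max}]"
            )
    return df


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("subject_id", "age", "group_label") if c in df.columns]
    cols += [c for c in item_ids() if c in df.columns]
    df[cols].to_csv(path, index=False, lineterminator="\r\n")


def read_labels_csv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    for col in ("subject_id",):
        if col not in df.columns:
            raise ValidationError(f"labels table must have a {col} column")
    label_col = "cluster" if "cluster" in df.columns else (
        "true_label" if "true_label" in df.columns else None)
    if label_col is None:
        raise ValidationError("labels table needs a cluster or true_label column")
    return pd.Series(df[label_col].to_numpy(), index=df["subject_id"].astype(str), name=label_col)


def write_labels_csv(labels: pd.Series, path: str | Path) -> None:
    out = labels.rename_axis("subject_id").reset_index()
    out.to_csv(path, index=False, lineterminator="\r\n")


def read_treatment_csv(path: str | Path) -> list[TreatmentRecord]:
    df = pd.read_csv(path)
    needed = {"subject_id", "therapy", "attempted", "responded"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"treatment table missing column(s): {', '.join(sorted(missing))}")
    return [
        TreatmentRecord(str(r.subject_id), str(r.therapy), bool(r.attempted), bool(r.responded))
        for r in df.itertuples()
    ]


def write_treatment_csv(records: list[TreatmentRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False, lineterminator="\r\n")
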