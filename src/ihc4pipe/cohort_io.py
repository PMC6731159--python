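"""CSV dialect for cohort tables.

Patient-level files carry one row per ``patient_id``; core-level files
carry ``patient_id`` + ``core_id`` and only marker columns, and are
aggregated to patient level on read.  Missing values are empty fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .scores import CoreMeasurement, aggregate_cores

__all__ = ["read_cohort", "write_cohort", "PATIENT_COLUMNS", "CORE_COLUMNS"]

MARKER_COLUMNS = {
    "er_pct": (0.0, 100.0),
    "pr_pct": (0.0, 100.0),
    "ki67_pct": (0.0, 100.0),
    "her2_herceptest": (0.0, 3.0),
}
BINARY_COLUMNS = [
    "er_clinical_pos", "pr_clinical_pos", "her2_clinical_pos",
    "endocrine_therapy", "chemotherapy",
]
PATIENT_COLUMNS = (
    ["patient_id"]
    + list(MARKER_COLUMNS)
    + BINARY_COLUMNS
    + ["age_years", "tumor_size_mm", "grade", "positive_nodes", "study",
       "time_years", "event", "latent_lp",
       "ihc4", "c_score", "predict_score", "subtype",
       "ihc4_z", "ihc4_quartile", "ihc4_high"]
)
CORE_COLUMNS = ["patient_id", "core_id"] + list(MARKER_COLUMNS)


class CohortValidationError(ValueError):
    pass


def _fail(path, row, msg):
    where = f"{path}, row {row}" if row is not None else str(path)
    raise CohortValidationError(f"{where}: {msg}")


def _validate_patient_table(df: pd.DataFrame, path) -> None:
    unknown = [c for c in df.columns if c not in PATIENT_COLUMNS]
    if unknown:
        _fail(path, None, f"unknown columns {unknown}")
    if "patient_id" not in df.columns:
        _fail(path, None, "missing patient_id column")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        row = int(dup.index[0]) + 2  # 1-based + header
        _fail(path, row, f"duplicate patient_id {dup.iloc[0]!r}")
    for col, (lo, hi) in MARKER_COLUMNS.items():
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & ((vals < lo) | (vals > hi) | vals.isna())
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            _fail(path, i + 2, f"{col}={df[col].iloc[i]!r} outside [{lo}, {hi}]")
    for col in BINARY_COLUMNS:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & ~vals.isin([0, 1])
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            _fail(path, i + 2, f"{col}={df[col].iloc[i]!r} is not binary")
    if "grade" in df.columns:
        bad = df["grade"].notna() & ~df["grade"].isin([1, 2, 3])
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            _fail(path, i + 2, f"grade={df['grade'].iloc[i]!r} not in {{1,2,3}}")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; core-level input is aggregated.

    Raises :class:`CohortValidationError` with the offending line number
    on schema violations.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "core_id" in df.columns:
        unknown = [c for c in df.columns if c not in CORE_COLUMNS]
        if unknown:
            _fail(path, None, f"unknown columns {unknown} in core-level file")
        rows = []
        for pid, part in df.groupby("patient_id", sort=True):
            cores = [
                CoreMeasurement(
                    core_id=str(r.core_id),
                    er_pct=None if pd.isna(r.er_pct) else float(r.er_pct),
                    pr_pct=None if pd.isna(r.pr_pct) else float(r.pr_pct),
                    ki67_pct=None if pd.isna(r.ki67_pct) else float(r.ki67_pct),
                    her2_herceptest=(
                        None if pd.isna(r.her2_herceptest) else int(r.her2_herceptest)
                    ),
                )
                for r in part.itertuples()
            ]
            panel = aggregate_cores(cores)
            rows.append(
                {
                    "patient_id": pid,
                    "er_pct": panel.er_pct,
                    "pr_pct": panel.pr_pct,
                    "ki67_pct": panel.ki67_pct,
                    "her2_herceptest": panel.her2_herceptest,
                }
            )
        return pd.DataFrame(rows)
    _validate_patient_table(df, path)
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table losslessly (default float repr, empty = NA)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
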