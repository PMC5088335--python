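"""Cohort CSV reading/writing with validation and exclusion accounting.

The cohort schema is a flat CSV (UTF-8, comma-separated, "." decimal, header
mandatory) with the columns in :data:`anthrorisk.indices.COHORT_COLUMNS`.
Rows failing validation (missing values, nonpositive measurements, malformed
indicators) are dropped and counted, never imputed; the eligibility gate
(nonpregnant adults) is applied separately with its own counts so cohort-size
accounting stays reproducible on any input.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SchemaError
from .indices import COHORT_COLUMNS, apply_eligibility

__all__ = ["load_cohort", "write_cohort", "validate_cohort_frame"]

logger = logging.getLogger(__name__)

_NUMERIC_COLUMNS = [c for c in COHORT_COLUMNS if c != "subject_id"]
_POSITIVE_COLUMNS = ["height_cm", "weight_kg", "waist_cm", "hip_cm"]
_INDICATOR_COLUMNS = ["female", "race_black", "died", "pregnant"]


def validate_cohort_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop rows violating the schema's value constraints; count what was dropped.

    Constraints: numeric fields present and finite; measurements strictly
    positive; indicators in {0, 1}; sample_weight >= 0; followup_years >= 0.
    """
    missing = sorted(set(COHORT_COLUMNS) - set(df.columns))
    if missing:
        raise SchemaError(f"cohort file is missing required columns: {missing}")
    work = df.copy()
    for col in _NUMERIC_COLUMNS:
        work[col] = pd.to_numeric(work[col], errors="coerce")

    ok = np.ones(len(work), dtype=bool)
    for col in _NUMERIC_COLUMNS:
        ok &= np.isfinite(work[col].to_numpy(dtype=float))
    for col in _POSITIVE_COLUMNS:
        ok &= work[col].to_numpy(dtype=float) > 0
    for col in _INDICATOR_COLUMNS:
        ok &= np.isin(work[col].to_numpy(dtype=float), (0.0, 1.0))
    ok &= work["sample_weight"].to_numpy(dtype=float) >= 0
    ok &= work["followup_years"].to_numpy(dtype=float) >= 0

    counts = {"n_rows": len(work), "n_dropped_invalid": int((~ok).sum())}
    if counts["n_dropped_invalid"]:
        logger.info(
            "dropped %d invalid row(s) of %d during validation",
            counts["n_dropped_invalid"], counts["n_rows"],
        )
    clean = work.loc[ok].reset_index(drop=True)
    for col in _INDICATOR_COLUMNS:
        clean[col] = clean[col].astype(int)
    return clean, counts


def load_cohort(path, gate: bool = True) -> pd.DataFrame:
    """Read, validate and (optionally) gate a cohort CSV.

    Returns a typed DataFrame; per-stage record counts are logged and attached
    as ``df.attrs["accounting"]``.
    """
    try:
        raw = pd.read_csv(path, dtype={"subject_id": str})
    except pd.errors.EmptyDataError as exc:
        raise InsufficientDataError(f"empty cohort file: {path}") from exc
    if len(raw) == 0:
        raise InsufficientDataError(f"cohort file has a header but no rows: {path}")
    clean, counts = validate_cohort_frame(raw)
    if gate:
        clean, gate_counts = apply_eligibility(clean)
        counts.update(gate_counts)
    clean.attrs["accounting"] = counts
    logger.info("loaded cohort %s: %s", path, counts)
    return clean


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table in the canonical column order."""
    missing = sorted(set(COHORT_COLUMNS) - set(df.columns))
    if missing:
        raise SchemaError(f"cohort frame is missing columns: {missing}")
    df[COHORT_COLUMNS].to_csv(path, index=False)
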