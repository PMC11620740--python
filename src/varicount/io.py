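"""Cohort CSV schema, estimate tables and exclusion logs.

The ingestion format is a plain CSV of gated flow-cytometry summary
frequencies, one row per animal x gated population:

required columns
    ``sample_id, replicate, timepoint, cell_type, condition,
    recorded_events, rfp_pct, yfp_pct, cfp_pct``
optional columns
    ``gfp_pct, cd45_1_pct, cd45_2_pct, myeloid_pct, t_pct, b_pct, flags``

Percent columns live on the 0-100 scale.  Estimates are written as a
tidy CSV (one row per group x marker) with a sibling
``*.exclusions.json`` log recording every dropped sample and why.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_core import EstimateResult
from .preprocess import GROUP_KEYS

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "SchemaError",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_estimates",
    "read_estimates",
]

REQUIRED_COLUMNS = (
    "sample_id", "replicate", "timepoint", "cell_type", "condition",
    "recorded_events", "rfp_pct", "yfp_pct", "cfp_pct",
)
OPTIONAL_COLUMNS = (
    "gfp_pct", "cd45_1_pct", "cd45_2_pct", "myeloid_pct", "t_pct", "b_pct",
    "flags",
)
_PERCENT_COLUMNS = (
    "rfp_pct", "yfp_pct", "cfp_pct", "gfp_pct", "cd45_1_pct", "cd45_2_pct",
    "myeloid_pct", "t_pct", "b_pct",
)


class SchemaError(ValueError):
    """Structured cohort-CSV schema violation."""

    def __init__(self, message: str, columns: Sequence[str] = (),
                 rows: Sequence[int] = ()):
        super().__init__(message)
        self.columns = tuple(columns)
        self.rows = tuple(rows)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort table.

    Raises :class:`SchemaError` naming missing required columns, rows
    with unparseable numerics, and rows with percentages outside
    [0, 100] (row numbers are 1-based data rows, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required columns: {', '.join(missing)}", columns=missing)

    numeric_cols = [c for c in df.columns
                    if c in _PERCENT_COLUMNS or c == "recorded_events"]
    bad_rows: set[int] = set()
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[df[col].notna() & coerced.isna()]
        bad_rows.update(int(i) + 1 for i in bad)
        df[col] = coerced
    if bad_rows:
        raise SchemaError(
            f"unparseable numeric values in rows: {sorted(bad_rows)}",
            rows=sorted(bad_rows))

    out_of_range: set[int] = set()
    for col in _PERCENT_COLUMNS:
        if col not in df.columns:
            continue
        vals = df[col]
        bad = df.index[vals.notna() & ((vals < 0) | (vals > 100))]
        out_of_range.update(int(i) + 1 for i in bad)
    if out_of_range:
        raise SchemaError(
            f"percentages outside [0, 100] in rows: {sorted(out_of_range)}",
            rows=sorted(out_of_range))

    if (df["recorded_events"].isna()).any() or (df["recorded_events"] < 0).any():
        bad = df.index[df["recorded_events"].isna() | (df["recorded_events"] < 0)]
        raise SchemaError(
            f"invalid recorded_events in rows: {[int(i) + 1 for i in bad]}",
            rows=[int(i) + 1 for i in bad])
    df["recorded_events"] = df["recorded_events"].astype(np.int64)
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise SchemaError(f"duplicate sample_id values: {dups}")
    return df


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def _estimate_row(r: EstimateResult) -> dict:
    row = dict(r.group or {k: "" for k in GROUP_KEYS})
    row.update(
        marker=r.marker,
        n_hat="" if r.n_hat is None else r.n_hat,
        fp_mean_hat="" if r.fp_mean_hat is None else r.fp_mean_hat,
        sigma_hat="" if r.sigma_hat is None else r.sigma_hat,
        cv_hat="" if r.cv_hat is None else r.cv_hat,
        n_samples_used=r.n_samples_used,
        n_hat_total="" if r.n_hat_total is None else r.n_hat_total,
        labeling_fraction="" if r.labeling_fraction is None else r.labeling_fraction,
        flags=";".join(r.flags),
    )
    return row


def write_estimates(results: Iterable[EstimateResult], path) -> Path:
    """Write a tidy estimates CSV plus a sibling JSON exclusion log.

    Flagged results are serialized with an empty ``n_hat`` and their
    flag string — never a numeric placeholder.  Returns the path of the
    exclusion log.  Floats round-trip at full precision.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to write")
    path = Path(path)
    pd.DataFrame([_estimate_row(r) for r in results]).to_csv(
        path, index=False, float_format="%.12g")
    log_path = path.with_suffix(".exclusions.json")
    log = [
        {"group": r.group, "marker": r.marker, "sample_id": sid, "reason": reason}
        for r in results for sid, reason in r.exclusions
    ]
    log_path.write_text(json.dumps(log, indent=1))
    return log_path


def read_estimates(path) -> pd.DataFrame:
    """Read back an estimates CSV (empty n_hat -> NaN)."""
    return pd.read_csv(path)
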