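"""Trial-table CSV dialect: reading, writing and validation.

The dialect is a plain UTF-8 comma-separated table with a fixed header,
one row per trial, ``NA`` as the missing marker and timing fields in
milliseconds with up to two decimals — the shape of the trial exports
produced by common stop-signal task runners.
"""

from __future__ import annotations

from typing import Sequence, Union

import pandas as pd

from .trial_model import (
    Environment,
    Response,
    Stimulus,
    coerce_staircase_label,
    TrialRecord,
    TrialType,
)

__all__ = [
    "COLUMNS",
    "MISSING",
    "TrialTableError",
    "records_to_frame",
    "frame_to_records",
    "read_trials",
    "write_trials",
    "validate_trials",
]

COLUMNS = [
    "participant_id",
    "environment",
    "phase_index",
    "block_index",
    "trial_index",
    "go_trial_index",
    "staircase_label",
    "trial_type",
    "stimulus",
    "response",
    "rt_ms",
    "ssd_intended_ms",
    "ssd_actual_ms",
    "stop_success",
]

MISSING = "NA"

_TIMING_COLS = ("rt_ms", "ssd_intended_ms", "ssd_actual_ms")
_INT_COLS = ("phase_index", "block_index", "trial_index")


class TrialTableError(ValueError):
    """Malformed trial table; message carries the offending row/column."""


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "participant_id": r.participant_id,
                "environment": r.environment.value,
                "phase_index": r.phase_index,
                "block_index": r.block_index,
                "trial_index": r.trial_index,
                "go_trial_index": r.go_trial_index,
                "staircase_label": getattr(r.staircase_label, "value", r.staircase_label),
                "trial_type": r.trial_type.value,
                "stimulus": r.stimulus.value,
                "response": r.response.value,
                "rt_ms": r.rt_ms,
                "ssd_intended_ms": r.ssd_intended_ms,
                "ssd_actual_ms": r.ssd_actual_ms,
                "stop_success": r.stop_success,
            }
        )
    df = pd.DataFrame(rows, columns=COLUMNS)
    if len(df):
        df["go_trial_index"] = df["go_trial_index"].astype("Int64")
        df["stop_success"] = df["stop_success"].astype("boolean")
    return df


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for idx, row in df.iterrows():
        records.append(_row_to_record(row, idx))
    return records


def _row_to_record(row: pd.Series, idx) -> TrialRecord:
    def opt_float(name: str):
        v = row[name]
        return None if pd.isna(v) else float(v)

    def opt_int(name: str):
        v = row[name]
        return None if pd.isna(v) else int(v)

    try:
        stop_success = row["stop_success"]
        return TrialRecord(
            participant_id=str(row["participant_id"]),
            environment=Environment(row["environment"]),
            phase_index=int(row["phase_index"]),
            block_index=int(row["block_index"]),
            trial_index=int(row["trial_index"]),
            go_trial_index=opt_int("go_trial_index"),
            staircase_label=coerce_staircase_label(row["staircase_label"]),
            trial_type=TrialType(row["trial_type"]),
            stimulus=Stimulus(row["stimulus"]),
            response=Response(row["response"]),
            rt_ms=opt_float("rt_ms"),
            ssd_intended_ms=opt_float("ssd_intended_ms"),
            ssd_actual_ms=opt_float("ssd_actual_ms"),
            stop_success=None if pd.isna(stop_success) else bool(stop_success),
        )
    except ValueError as exc:
        raise TrialTableError(f"row {idx}: {exc}") from exc


def validate_trials(df: pd.DataFrame, *, source: str = "<frame>") -> None:
    """Check the table against all trial invariants.

    Raises :class:`TrialTableError` naming the first offending row.
    """
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise TrialTableError(f"{source}: missing columns {missing_cols}")
    frame_to_records(df[COLUMNS])


def write_trials(table: Union[pd.DataFrame, Sequence[TrialRecord]], path) -> None:
    """Write a trial table in the CSV dialect (two-decimal timing, NA)."""
    df = table if isinstance(table, pd.DataFrame) else records_to_frame(table)
    out = df[COLUMNS].copy()
    for col in _TIMING_COLS:
        out[col] = out[col].map(lambda v: MISSING if pd.isna(v) else f"{float(v):.2f}")
    out["stop_success"] = out["stop_success"].map(
        lambda v: MISSING if pd.isna(v) else str(bool(v))
    )
    out["go_trial_index"] = out["go_trial_index"].map(
        lambda v: MISSING if pd.isna(v) else str(int(v))
    )
    out.to_csv(path, index=False, encoding="utf-8")


def read_trials(path, *, validate: bool = True) -> pd.DataFrame:
    """Read a trial-table CSV, validating every row's invariants."""
    df = pd.read_csv(
        path,
        na_values=[MISSING],
        keep_default_na=False,
        dtype={"participant_id": str},
        encoding="utf-8",
    )
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise TrialTableError(f"{path}: missing columns {missing_cols}")
    for col in _TIMING_COLS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["go_trial_index"] = pd.to_numeric(df["go_trial_index"], errors="coerce").astype("Int64")
    df["stop_success"] = df["stop_success"].map(
        {"True": True, "False": False, True: True, False: False}
    ).astype("boolean")
    if validate:
        for idx, row in df.iterrows():
            try:
                _row_to_record(row, idx)
            except TrialTableError as exc:
                raise TrialTableError(f"{path}: line {idx + 2}: {exc}") from exc
    return df
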