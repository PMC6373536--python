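"""Reading and writing the canonical CSV schemas."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .types import PARTICIPANT_COLUMNS, TRIAL_COLUMNS

__all__ = [
    "read_trials_csv",
    "write_trials_csv",
    "read_participants_csv",
    "write_participants_csv",
]


class SchemaError(ValueError):
    """Raised when a CSV does not match the expected schema."""


def read_trials_csv(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a trial CSV; ``column_map`` renames external headers to the
    canonical schema. Unknown extra columns are preserved; malformed RT
    rows raise with their file line numbers."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    if len(df):
        rt = pd.to_numeric(df["rt_ms"], errors="coerce")
        bad = df.index[rt.isna() | (rt <= 0)]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
            raise SchemaError(f"{path}: non-numeric or non-positive rt_ms at "
                              f"line(s) {lines}")
        df["rt_ms"] = rt.astype(float)
        df["trial_index"] = df["trial_index"].astype(int)
        if df["correct"].dtype != bool:
            df["correct"] = (
                df["correct"].astype(str).str.strip().str.lower().map(
                    {"true": True, "false": False, "1": True, "0": False}
                )
            )
            if df["correct"].isna().any():
                raise SchemaError(f"{path}: unparseable 'correct' values")
            df["correct"] = df["correct"].astype(bool)
    else:
        df = df.astype({"rt_ms": float, "trial_index": int, "correct": bool})
    ordered = TRIAL_COLUMNS + [c for c in df.columns if c not in TRIAL_COLUMNS]
    return df[ordered]


def write_trials_csv(trials: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"cannot write trials: missing columns {missing}")
    trials.to_csv(path, index=False)


def read_participants_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    return df


def write_participants_csv(participants: pd.DataFrame, path: str | Path) -> None:
    participants.to_csv(path, index=False)
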