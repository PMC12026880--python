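"""Readers and writers for the pipeline's CSV dialects.

All files are plain UTF-8 CSV with a header row.  Datetimes are ISO-8601,
timezone-naive local clock.

* epochs:   ``participant_id,start_iso8601,duration_s,state,mets``
* roster:   ``participant_id,arrival_iso8601,departure_iso8601``
* status:   ``participant_id,is_day_worker,consented,wore_device,has_exam,n_wear_days``
* participants: wide table of covariates, outcomes and day-type behaviour means
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .types import EpochState, ValidationError

EPOCH_COLUMNS = ("participant_id", "start_iso8601", "duration_s", "state", "mets")
ROSTER_COLUMNS = ("participant_id", "arrival_iso8601", "departure_iso8601")
STATUS_COLUMNS = (
    "participant_id", "is_day_worker", "consented", "wore_device", "has_exam",
    "n_wear_days",
)

_VALID_STATES = {s.value for s in EpochState}


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns: {missing}")


def read_epochs_csv(path: str | Path) -> pd.DataFrame:
    """Read the epoch dialect into the internal epoch table."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, EPOCH_COLUMNS, path)
    bad_states = set(df["state"].astype(str).unique()) - _VALID_STATES
    if bad_states:
        raise ValidationError(f"{path}: unknown epoch states: {sorted(bad_states)}")
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "start": pd.to_datetime(df["start_iso8601"], format="ISO8601"),
            "duration_s": pd.to_numeric(df["duration_s"]),
            "state": df["state"].astype(str),
            "mets": pd.to_numeric(df["mets"], errors="coerce"),
        }
    )
    if (out["duration_s"] <= 0).any():
        raise ValidationError(f"{path}: non-positive epoch duration")
    return out


def write_epochs_csv(epochs: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "participant_id": epochs["participant_id"],
            "start_iso8601": pd.to_datetime(epochs["start"]).dt.strftime("%Y-%m-%dT%H:%M:%S"),
            "duration_s": epochs["duration_s"],
            "state": epochs["state"],
            "mets": epochs["mets"],
        }
    )
    out.to_csv(path, index=False)


def read_roster_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, ROSTER_COLUMNS, path)
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "arrival": pd.to_datetime(df["arrival_iso8601"], format="ISO8601"),
            "departure": pd.to_datetime(df["departure_iso8601"], format="ISO8601"),
        }
    )
    if (out["arrival"] >= out["departure"]).any():
        raise ValidationError(f"{path}: roster interval with arrival >= departure")
    return out


def write_roster_csv(roster: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "participant_id": roster["participant_id"],
            "arrival_iso8601": pd.to_datetime(roster["arrival"]).dt.strftime("%Y-%m-%dT%H:%M:%S"),
            "departure_iso8601": pd.to_datetime(roster["departure"]).dt.strftime("%Y-%m-%dT%H:%M:%S"),
        }
    )
    out.to_csv(path, index=False)


def read_status_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, STATUS_COLUMNS, path)
    for col in ("is_day_worker", "consented", "wore_device", "has_exam"):
        df[col] = df[col].astype(bool)
    df["n_wear_days"] = pd.to_numeric(df["n_wear_days"]).astype(int)
    return df


def write_status_csv(status: pd.DataFrame, path: str | Path) -> None:
    status.to_csv(path, index=False)


def read_participants_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, ("participant_id",), path)
    return df


def write_participants_csv(participants: pd.DataFrame, path: str | Path) -> None:
    participants.to_csv(path, index=False)
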