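"""Plain-text I/O for trial tables and ratings.

Trial CSVs use the finger-report coding of the task: ``response`` is 1 for
"simultaneous", 2 for "successive", and NA when the participant gave no
report.  In-memory tables use the string categories throughout.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .trial_prep import (
    RESPONSE_NONE,
    RESPONSE_SIMULTANEOUS,
    RESPONSE_SUCCESSIVE,
    TRIAL_COLUMNS,
    as_trial_frame,
)

_RESPONSE_TO_CODE = {RESPONSE_SIMULTANEOUS: "1", RESPONSE_SUCCESSIVE: "2",
                     RESPONSE_NONE: "NA"}
_CODE_TO_RESPONSE = {1: RESPONSE_SIMULTANEOUS, 2: RESPONSE_SUCCESSIVE}


def write_trials_csv(trials: pd.DataFrame, path: str | Path) -> None:
    frame = as_trial_frame(trials).copy()
    frame["response"] = frame["response"].map(_RESPONSE_TO_CODE)
    frame.to_csv(path, index=False, na_rep="NA")


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    """Read a trial CSV, raising a parse error that names the offending line."""
    frame = pd.read_csv(path, na_values=["NA"],
                        keep_default_na=False,
                        dtype={"participant_id": str, "condition": str})
    missing = set(TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(
            f"{path}: missing columns {sorted(missing)} in header (line 1)")
    resp = pd.to_numeric(frame["response"], errors="coerce")
    bad = frame["response"].notna() & resp.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ValueError(
            f"{path}: line {line}: unparseable response "
            f"{frame['response'][bad.idxmax()]!r} (expected 1, 2 or NA)")
    invalid = resp.notna() & ~resp.isin(list(_CODE_TO_RESPONSE))
    if invalid.any():
        line = int(invalid.idxmax()) + 2
        raise ValueError(
            f"{path}: line {line}: response code {resp[invalid.idxmax()]} "
            f"is not 1, 2 or NA")
    frame["response"] = resp.map(_CODE_TO_RESPONSE).fillna(RESPONSE_NONE)
    for col in ("nominal_soa_ms", "actual_soa_ms"):
        frame[col] = pd.to_numeric(frame[col])
    frame["session"] = pd.to_numeric(frame["session"]).astype(int)
    frame["trial_index"] = pd.to_numeric(frame["trial_index"]).astype(int)
    return frame[TRIAL_COLUMNS + [c for c in frame.columns
                                  if c not in TRIAL_COLUMNS]]


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"participant_id": str, "condition": str,
                                     "dimension": str})
    required = {"participant_id", "condition", "dimension", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: ratings table missing {sorted(missing)}")
    frame["value"] = pd.to_numeric(frame["value"])
    return frame
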