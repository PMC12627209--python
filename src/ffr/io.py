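"""Session CSV round-tripping.

A session table has one row per trial with columns
``observer_id, trial_index, condition, mean_hue, test_offset, response``.
The display itself is not stored: disk hues are a deterministic function
of (condition, mean_hue), so they are rebuilt on read.  The response
column is empty until an observer (human or simulated) fills it.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, List, Union

import pandas as pd

from .stimuli import ColorWheel, Session, StimulusError, WHEEL48, make_trial

__all__ = ["SessionSchemaError", "sessions_to_frame", "write_sessions", "read_sessions"]

COLUMNS = ["observer_id", "trial_index", "condition", "mean_hue", "test_offset", "response"]


class SessionSchemaError(ValueError):
    """Session table violates the expected schema."""


def sessions_to_frame(sessions: Union[Session, Iterable[Session]]) -> pd.DataFrame:
    if isinstance(sessions, Session):
        sessions = [sessions]
    rows = []
    for session in sessions:
        for i, t in enumerate(session.trials):
            rows.append(
                (session.observer_id, i, t.condition, t.mean_hue, t.test_offset,
                 t.response)
            )
    frame = pd.DataFrame(rows, columns=COLUMNS)
    frame["response"] = frame["response"].astype("Int64")
    return frame


def write_sessions(sessions: Union[Session, Iterable[Session]], path) -> None:
    """Write one or more sessions to a UTF-8 CSV with a header row."""
    sessions_to_frame(sessions).to_csv(path, index=False, encoding="utf-8")


def read_sessions(
    path,
    wheel: ColorWheel = WHEEL48,
    require_responses: bool = False,
) -> List[Session]:
    """Read sessions back from CSV, rebuilding each trial's display.

    With ``require_responses=True`` missing or out-of-range responses are
    reported with their (1-based, header-inclusive) row numbers.
    """
    frame = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SessionSchemaError(f"missing required columns: {missing}")
    frame["response"] = frame["response"].astype("Int64")
    if require_responses:
        bad_rows = frame.index[frame["response"].isna()] + 2
        if len(bad_rows):
            shown = ", ".join(map(str, bad_rows[:10]))
            more = "..." if len(bad_rows) > 10 else ""
            raise SessionSchemaError(
                f"column 'response' is empty at rows {shown}{more} "
                f"({len(bad_rows)} rows total)"
            )
        out_of_range = frame.index[(frame["response"] < 0) | (frame["response"] > 8)] + 2
        if len(out_of_range):
            raise SessionSchemaError(
                "column 'response' outside the 0-8 slider range at rows "
                + ", ".join(map(str, out_of_range[:10]))
            )
    sessions = []
    for observer_id, group in frame.groupby("observer_id", sort=False):
        group = group.sort_values("trial_index")
        trials = []
        for row in group.itertuples(index=True):
            try:
                trial = make_trial(
                    row.condition, int(row.mean_hue), int(row.test_offset), wheel
                )
            except StimulusError as err:
                raise SessionSchemaError(f"row {row.Index + 2}: {err}") from err
            if not pd.isna(row.response):
                trial = replace(trial, response=int(row.response))
            trials.append(trial)
        sessions.append(Session(str(observer_id), trials))
    return sessions
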