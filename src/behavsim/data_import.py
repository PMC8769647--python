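"""Parse session data files into an in-memory :class:`Session`.

Two complementary representations of the behavioural record are built, the
forms analyses typically want:

1. ``times`` -- a dict mapping each event/state name to a sorted NumPy array
   of occurrence / state-entry times (ms);
2. ``ordered`` -- the events and state entries in file order, as named tuples
   ``Datum(name, time, kind)``.

Counts always agree between the two.  State *exit* times are not stored in
the file; :func:`state_intervals` reconstructs occupancy intervals from
consecutive state entries, closing the final one at the session end time.
"""

from __future__ import annotations

import json
from collections import namedtuple
from typing import Dict, List, Optional, Tuple

import numpy as np

Datum = namedtuple("Datum", ["name", "time", "kind"])  # kind: 'state' | 'event'

_HEADER_KEYS = ("experiment", "task", "task_hash", "subject", "start_time", "seed")


class SessionParseError(ValueError):
    """Malformed session file (message carries the 1-based line number)."""


class Session:
    """Parsed session: header fields plus the two data representations.

    Attributes
    ----------
    experiment, task_name, task_hash, subject, start_time : str
    seed : int
    state_ids, event_ids : dict
    times : dict[str, np.ndarray]
    ordered : list[Datum]
    prints : list[(t, text)]
    variable_changes : list[(t, name, value)]
    errors : list[(t, traceback_text)]
    end_time : int or None
    """

    def __init__(self, path):
        self.path = str(path)
        info: Dict[str, str] = {}
        self.state_ids: Dict[str, int] = {}
        self.event_ids: Dict[str, int] = {}
        self.ordered: List[Datum] = []
        self.prints: List[Tuple[int, str]] = []
        self.variable_changes: List[Tuple[int, str, object]] = []
        self.errors: List[Tuple[int, str]] = []
        self.end_time: Optional[int] = None

        id_to_name: Dict[int, Tuple[str, str]] = {}
        last_t = 0
        seen_data = False

        with open(self.path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                code, _, rest = line.partition(" ")

                def fail(msg):
                    raise SessionParseError(f"{self.path}: line {lineno}: {msg}")

                if code == "I":
                    key, _, value = rest.partition(" ")
                    info[key] = value
                elif code == "S":
                    self.state_ids = {str(k): int(v) for k, v in json.loads(rest).items()}
                elif code == "E":
                    self.event_ids = {str(k): int(v) for k, v in json.loads(rest).items()}
                    for name, i in self.state_ids.items():
                        id_to_name[i] = (name, "state")
                    for name, i in self.event_ids.items():
                        if i in id_to_name:
                            fail(f"ID {i} used for both a state and an event")
                        id_to_name[i] = (name, "event")
                elif code in ("D", "P", "V", "!", "Z"):
                    if not id_to_name and code == "D":
                        fail("data line before ID maps")
                    missing = [k for k in _HEADER_KEYS if k not in info]
                    if missing:
                        fail(f"data line before complete header (missing {missing})")
                    fields = rest.split(" ", 1)
                    try:
                        t = int(fields[0])
                    except (ValueError, IndexError):
                        fail(f"bad timestamp in {line!r}")
                    if t < last_t:
                        fail(f"non-monotone timestamp {t} after {last_t}")
                    last_t = t
                    if code == "D":
                        seen_data = True
                        try:
                            ident = int(fields[1])
                        except (ValueError, IndexError):
                            fail(f"bad ID in {line!r}")
                        if ident not in id_to_name:
                            fail(f"unknown ID {ident}")
                        name, kind = id_to_name[ident]
                        self.ordered.append(Datum(name, t, kind))
                    elif code == "P":
                        self.prints.append((t, fields[1] if len(fields) > 1 else ""))
                    elif code == "V":
                        name, _, payload = fields[1].partition(" ")
                        try:
                            value = json.loads(payload)
                        except json.JSONDecodeError:
                            fail(f"bad variable value in {line!r}")
                        self.variable_changes.append((t, name, value))
                    elif code == "!":
                        try:
                            self.errors.append((t, json.loads(fields[1])))
                        except (json.JSONDecodeError, IndexError):
                            fail(f"bad error payload in {line!r}")
                    elif code == "Z":
                        self.end_time = t
                else:
                    raise SessionParseError(
                        f"{self.path}: line {lineno}: unknown line code {code!r}")

        missing = [k for k in _HEADER_KEYS if k not in info]
        if missing:
            raise SessionParseError(f"{self.path}: missing header fields: {missing}")
        self.experiment = info["experiment"]
        self.task_name = info["task"]
        self.task_hash = info["task_hash"]
        self.subject = info["subject"]
        self.start_time = info["start_time"]
        try:
            self.seed = int(info["seed"])
        except ValueError:
            raise SessionParseError(f"{self.path}: non-integer seed {info['seed']!r}")

        self.times: Dict[str, np.ndarray] = {
            name: np.array([d.time for d in self.ordered if d.name == name], dtype=np.int64)
            for name in list(self.state_ids) + list(self.event_ids)
        }
        self._seen_data = seen_data

    def __repr__(self):
        return (f"Session({self.subject!r}, task={self.task_name!r}, "
                f"{len(self.ordered)} records, end={self.end_time})")


def parse_session(path) -> Session:
    """Parse a session data file written by :mod:`behavsim.session_log`."""
    return Session(path)


def state_intervals(session: Session, state_name: str) -> List[Tuple[int, int]]:
    """[t_entry, t_exit) occupancy intervals of one state.

    Exits are inferred from the next state entry; the final interval is
    closed by the session end time.
    """
    if state_name not in session.state_ids:
        raise KeyError(f"state {state_name!r} not in this session's ID map")
    intervals: List[Tuple[int, int]] = []
    current_entry: Optional[int] = None
    for d in session.ordered:
        if d.kind != "state":
            continue
        if current_entry is not None:
            intervals.append((current_entry, d.time))
            current_entry = None
        if d.name == state_name:
            current_entry = d.time
    if current_entry is not None:
        end = session.end_time if session.end_time is not None else current_entry
        intervals.append((current_entry, end))
    return intervals


def session_summary_counts(session: Session) -> Dict[str, int]:
    """Occurrence count per event/state name (equals ``len(times[name])``)."""
    return {name: int(arr.size) for name, arr in session.times.items()}


def export_times_csv(session: Session, path) -> None:
    """Write the ``times`` representation as a long-format CSV
    (columns: name, kind, time_ms)."""
    import pandas as pd

    rows = [(d.name, d.kind, d.time) for d in session.ordered]
    pd.DataFrame(rows, columns=["name", "kind", "time_ms"]).to_csv(str(path), index=False)
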