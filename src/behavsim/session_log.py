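"""Line-oriented session data files.

Each session is a UTF-8 text file.  Grammar (one record per line):

.. code-block:: text

    I <key> <value>          header info: experiment, task, task_hash,
                             subject, start_time, seed  (in that order)
    S <json object>          state name -> integer ID map
    E <json object>          event name -> integer ID map
    V <t> <name> <json>      variable changed away from its task-file default
    D <t> <id>               event occurrence or state entry at <t> ms
    P <t> <text>             user print line
    ! <t> <json string>      error traceback (JSON-encoded, single line)
    Z <t>                    end of session

States and events share one ID space (states first), so a ``D`` line is
unambiguous.  Timestamps are integer milliseconds from run start and
non-decreasing within a file.  Variables changed before the run give ``V``
lines at t=0 ahead of the first ``D`` line, so a data file documents its own
parameter deviations.

Analog channel data goes to companion binary ``.pca`` files of little-endian
(int32 timestamp ms, int32 value) pairs, one file per channel.

Task source files are archived next to the data with a short content hash
(CRC-32 as 8 lowercase hex chars) in the filename that is also recorded in
the session header, so the exact task version behind any data file can
always be identified.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np


def task_file_hash(source_text: str) -> str:
    """CRC-32 of the task source, rendered as 8 lowercase hex characters."""
    return format(zlib.crc32(source_text.encode("utf-8")) & 0xFFFFFFFF, "08x")


def archive_task_file(source_text: str, task_name: str, directory) -> str:
    """Write ``<task_name>_<digest>.py`` into ``directory``; return the path."""
    digest = task_file_hash(source_text)
    path = os.path.join(str(directory), f"{task_name}_{digest}.py")
    if not os.path.exists(path):  # identical content -> identical name
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(source_text)
    return path


@dataclass(frozen=True)
class SessionHeader:
    experiment: str
    task_name: str
    task_hash: str
    subject: str
    start_time: str  # ISO 8601
    seed: int


def build_id_maps(states, events) -> Tuple[dict, dict]:
    """Shared ID space: states numbered first, then events."""
    state_ids = {name: i + 1 for i, name in enumerate(states)}
    event_ids = {name: i + 1 + len(state_ids) for i, name in enumerate(events)}
    return state_ids, event_ids


class SessionWriter:
    """Writable session file.  Header and ID maps precede any data line;
    timestamps must be non-decreasing; an existing path is refused."""

    def __init__(self, path, header: SessionHeader, state_ids: dict,
                 event_ids: dict, overwrite: bool = False):
        path = str(path)
        if os.path.exists(path) and not overwrite:
            raise FileExistsError(f"refusing to overwrite session file {path}")
        self.path = path
        self.header = header
        self.state_ids = dict(state_ids)
        self.event_ids = dict(event_ids)
        self._last_t = 0
        self._fh = open(path, "w", encoding="utf-8", newline="\n")
        self.closed = False
        for key, value in (("experiment", header.experiment),
                           ("task", header.task_name),
                           ("task_hash", header.task_hash),
                           ("subject", header.subject),
                           ("start_time", header.start_time),
                           ("seed", header.seed)):
            self._fh.write(f"I {key} {value}\n")
        self._fh.write("S " + json.dumps(self.state_ids) + "\n")
        self._fh.write("E " + json.dumps(self.event_ids) + "\n")

    # -- line primitives ---------------------------------------------------

    def _check_open(self):
        if self.closed:
            raise ValueError("session file already closed")

    def _check_t(self, t) -> int:
        t = int(t)
        if t < self._last_t:
            raise ValueError(f"non-monotone timestamp: {t} after {self._last_t}")
        self._last_t = t
        return t

    def log_state(self, t: int, name: str) -> None:
        self._check_open()
        if name not in self.state_ids:
            raise KeyError(f"state {name!r} has no ID in this session")
        self._fh.write(f"D {self._check_t(t)} {self.state_ids[name]}\n")

    def log_event(self, t: int, name: str) -> None:
        self._check_open()
        if name not in self.event_ids:
            raise KeyError(f"event {name!r} has no ID in this session")
        self._fh.write(f"D {self._check_t(t)} {self.event_ids[name]}\n")

    def log_print(self, t: int, text: str) -> None:
        self._check_open()
        text = str(text)
        if "\n" in text or "\r" in text:
            raise ValueError("print text must be a single line")
        self._fh.write(f"P {self._check_t(t)} {text}\n")

    def log_variable(self, t: int, name: str, value) -> None:
        self._check_open()
        self._fh.write(f"V {self._check_t(t)} {name} {json.dumps(value)}\n")

    def log_error(self, t: int, traceback_text: str) -> None:
        self._check_open()
        self._fh.write(f"! {self._check_t(t)} {json.dumps(traceback_text)}\n")

    def log_end(self, t: int) -> None:
        """Write the end-of-session line and close the file."""
        self._check_open()
        self._fh.write(f"Z {self._check_t(t)}\n")
        self.close()

    def flush(self) -> None:
        if not self.closed:
            self._fh.flush()

    def close(self) -> None:
        if not self.closed:
            self._fh.close()
            self.closed = True


# -- analog companion files ---------------------------------------------------

def write_analog(path, times, values) -> None:
    """Write (int32 ms timestamp, int32 value) interleaved pairs, little-endian."""
    times = np.asarray(times)
    values = np.asarray(values)
    if times.shape != values.shape:
        raise ValueError("times and values must have equal length")
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("analog samples must be timestamp-sorted")
    interleaved = np.empty(2 * times.size, dtype="<i4")
    interleaved[0::2] = times.astype("<i4")
    interleaved[1::2] = values.astype("<i4")
    interleaved.tofile(str(path))


def read_analog(path) -> Tuple[np.ndarray, np.ndarray]:
    """Read a ``.pca`` file back as (times, values) int32 arrays."""
    raw = np.fromfile(str(path), dtype="<i4")
    if raw.size % 2:
        raise ValueError(f"truncated analog file: {path}")
    return raw[0::2].copy(), raw[1::2].copy()


def analog_path(session_path, channel_name: str) -> str:
    base, _ = os.path.splitext(str(session_path))
    return f"{base}_{channel_name}.pca"
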