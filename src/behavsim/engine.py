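"""Extended-state-machine task engine.

A task is a set of named states and events plus one *state behaviour
function* per state.  Whenever an event occurs, the behaviour function of the
current state is called with the event name; the reserved pseudo-events
``entry`` and ``exit`` are delivered when a state is entered or left.  An
optional ``all_states`` hook sees every externally generated event before the
state behaviour and may suppress it by returning True, which lets tasks run
logic (session timers, global stimuli) in parallel with the main state set.

Because behaviour functions may read and write task variables and call
arbitrary code, tasks are *extended* state machines: the response to an event
depends on the current state plus stored context, not on the state alone.

Behaviour functions receive the running :class:`Engine` as their first
argument and use its API: ``run.goto_state``, ``run.timed_goto_state``,
``run.set_event_timer``, ``run.v`` (variables), ``run.hw`` (virtual
hardware), ``run.print``, ``run.rng`` (seeded random generator) and
``run.stop``.
"""

from __future__ import annotations

import copy
import traceback
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .clock import KIND_EVENT, KIND_STATE, Scheduler, TimerEntry

RESERVED_EVENTS = ("entry", "exit")

#: one in-memory log record; ``kind`` is state_entry | event | print |
#: variable_change | error | end.
Record = namedtuple("Record", ["kind", "t", "payload"])


class TaskError(RuntimeError):
    """Misuse of the engine API by task code or by the caller."""


@dataclass
class TaskDefinition:
    """Declarative description of a task.

    ``behaviour`` maps each state name to a callable ``fn(run, event)``;
    ``all_states``, if given, is ``fn(run, event) -> bool`` where a True
    return suppresses delivery to the state behaviour.
    """

    name: str
    states: Sequence[str]
    events: Sequence[str]
    initial_state: str
    behaviour: Mapping[str, Callable]
    all_states: Optional[Callable] = None
    variables: dict = field(default_factory=dict)


def validate_task(defn: TaskDefinition) -> list:
    """Return a list of invariant violations (empty iff the task is valid)."""
    problems = []
    for group, names in (("state", defn.states), ("event", defn.events)):
        for name in names:
            if not isinstance(name, str) or not name:
                problems.append(f"{group} name must be a non-empty string: {name!r}")
            elif any(ch.isspace() for ch in name):
                problems.append(f"{group} name contains whitespace: {name!r}")
            if name in RESERVED_EVENTS:
                problems.append(f"{group} name {name!r} is reserved")
        if len(set(names)) != len(list(names)):
            problems.append(f"duplicate {group} names: {sorted(names)}")
    overlap = set(defn.states) & set(defn.events)
    if overlap:
        problems.append(f"names used as both state and event: {sorted(overlap)}")
    if defn.initial_state not in defn.states:
        problems.append(f"initial_state {defn.initial_state!r} is not a declared state")
    for state in defn.states:
        if state not in defn.behaviour:
            problems.append(f"state {state!r} has no behaviour function")
    for state in defn.behaviour:
        if state not in defn.states:
            problems.append(f"behaviour given for undeclared state {state!r}")
    for vname in defn.variables:
        if not isinstance(vname, str) or not vname or any(ch.isspace() for ch in vname):
            problems.append(f"bad variable name: {vname!r}")
    return problems


class VarsProxy:
    """Attribute/item access to task variables (declared names only)."""

    __slots__ = ("_vars",)

    def __init__(self, variables: dict):
        object.__setattr__(self, "_vars", variables)

    def __getattr__(self, name):
        try:
            return self._vars[name]
        except KeyError:
            raise AttributeError(f"undeclared task variable {name!r}") from None

    def __setattr__(self, name, value):
        if name not in self._vars:
            raise AttributeError(f"undeclared task variable {name!r}")
        self._vars[name] = value

    def __getitem__(self, name):
        try:
            return self._vars[name]
        except KeyError:
            raise KeyError(f"undeclared task variable {name!r}") from None

    def __setitem__(self, name, value):
        if name not in self._vars:
            raise KeyError(f"undeclared task variable {name!r}")
        self._vars[name] = value


class Engine:
    """One running (or runnable) instance of a task on a scheduler.

    Parameters
    ----------
    defn:
        The task definition; must be valid (see :func:`validate_task`).
    scheduler:
        The simulated clock / event queue the run executes on.  The engine
        installs itself as the scheduler's dispatch target.
    board:
        Optional virtual hardware (exposed to task code as ``run.hw``).
    writer:
        Optional open :class:`behavsim.session_log.SessionWriter`; every log
        record is mirrored to it.
    seed:
        Seed for the per-run random generator ``run.rng`` (recorded in the
        session header by the caller).
    """

    def __init__(self, defn: TaskDefinition, scheduler: Scheduler, board=None,
                 writer=None, seed: int = 0):
        problems = validate_task(defn)
        if problems:
            raise ValueError("invalid task definition: " + "; ".join(problems))
        self.defn = defn
        self.sched = scheduler
        self.board = board
        self.writer = writer
        self.seed = seed
        self.rng = np.random.default_rng([seed, 0])
        self._vars = copy.deepcopy(dict(defn.variables))
        self.v = VarsProxy(self._vars)
        self.scratch: dict = {}  # task-private storage (never logged)
        self.phase = "not_started"  # not_started | running | stopped | errored
        self.current_state: Optional[str] = None
        self.log: list = []  # Record tuples, in order
        self._state_listeners: list = []
        self._in_exit = False
        self._state_timers: list = []
        scheduler.dispatch = self._dispatch
        scheduler.known_events = set(defn.events)
        if writer is not None:
            scheduler.flush_hook = writer.flush

    # -- hardware ----------------------------------------------------------

    @property
    def hw(self):
        if self.board is None:
            raise TaskError("task accessed run.hw but no virtual hardware is attached")
        return self.board

    # -- logging -----------------------------------------------------------

    def _log(self, kind: str, t: int, payload) -> None:
        self.log.append(Record(kind, t, payload))
        w = self.writer
        if w is None:
            return
        if kind == "state_entry":
            w.log_state(t, payload)
        elif kind == "event":
            w.log_event(t, payload)
        elif kind == "print":
            w.log_print(t, payload)
        elif kind == "variable_change":
            w.log_variable(t, payload[0], payload[1])
        elif kind == "error":
            w.log_error(t, payload)
        elif kind == "end":
            w.log_end(t)

    # -- run lifecycle -------------------------------------------------------

    def start_run(self) -> None:
        """Enter the initial state at t=0 (dispatching its ``entry`` event)."""
        if self.phase != "not_started":
            raise TaskError(f"start_run on a {self.phase} engine")
        self.phase = "running"
        try:
            self._enter_state(self.defn.initial_state)
        except Exception as exc:  # error in an entry handler
            self._error(exc)

    def stop_run(self) -> dict:
        """Disarm all timers, log the end record, halt the scheduler."""
        if self.phase != "running":
            raise TaskError(f"stop_run on a {self.phase} engine")
        self.sched.disarm_all()
        self.phase = "stopped"
        self._log("end", self.sched.now, None)
        self.sched.halt()
        return self.summary()

    stop = stop_run

    def run(self, duration_ms: float) -> dict:
        """Convenience lifecycle: start, advance to ``duration_ms``, stop.

        The run may end earlier if task code calls ``run.stop()`` or an error
        occurs.  Returns the run summary.
        """
        if self.phase == "not_started":
            self.start_run()
        if self.phase == "running":
            self.sched.advance_to(duration_ms)
        if self.phase == "running":
            self.stop_run()
        return self.summary()

    def summary(self) -> dict:
        counts: dict = {}
        for rec in self.log:
            counts[rec.kind] = counts.get(rec.kind, 0) + 1
        return {
            "task": self.defn.name,
            "phase": self.phase,
            "end_time_ms": self.sched.now,
            "record_counts": counts,
            "variables": dict(self._vars),
        }

    def _error(self, exc: Exception) -> None:
        tb = "".join(traceback.format_exception(type(exc), exc, exc.__traceback__))
        self._log("error", self.sched.now, tb)
        self.phase = "errored"
        self._log("end", self.sched.now, None)
        self.sched.halt()

    # -- event processing ----------------------------------------------------

    def _dispatch(self, item) -> None:
        """Scheduler callback: route one due item into the state machine."""
        if self.phase != "running":
            return
        try:
            if item.kind == KIND_STATE:
                self.goto_state(item.target)
            else:
                self.process_event(item.target, source=item.source)
        except Exception as exc:
            self._error(exc)

    def process_event(self, name: str, source: str = "api") -> None:
        """Deliver a declared event to the machine (all_states first)."""
        if self.phase != "running":
            raise TaskError(f"process_event on a {self.phase} engine")
        if name in RESERVED_EVENTS:
            raise TaskError(f"{name!r} is reserved and cannot be raised as an event")
        if name not in self.defn.events:
            raise TaskError(f"unknown event {name!r}")
        self._log("event", self.sched.now, name)
        suppressed = False
        if self.defn.all_states is not None:
            suppressed = self.defn.all_states(self, name) is True
        if not suppressed and self.phase == "running":
            self.defn.behaviour[self.current_state](self, name)

    def _enter_state(self, name: str) -> None:
        self.current_state = name
        self._log("state_entry", self.sched.now, name)
        self.defn.behaviour[name](self, "entry")
        for listener in self._state_listeners:
            listener(name, self.sched.now)

    def goto_state(self, name: str) -> None:
        """Transition: exit current state, enter ``name``.

        Any pending timed state transition is disarmed; a transition
        requested from within an exit handler is an error (recursion guard).
        """
        if self.phase != "running":
            raise TaskError(f"goto_state on a {self.phase} engine")
        if name not in self.defn.states:
            raise TaskError(f"goto_state to unknown state {name!r}")
        if self._in_exit:
            raise TaskError("goto_state called from within an exit handler")
        if self.current_state is not None:
            self._in_exit = True
            try:
                self.defn.behaviour[self.current_state](self, "exit")
            finally:
                self._in_exit = False
        self._disarm_state_timers()
        self._enter_state(name)

    def add_state_listener(self, fn: Callable[[str, int], None]) -> None:
        """Register ``fn(state_name, t)``, called after each state's entry
        handler has run.  Used by closed-loop agents driving virtual inputs."""
        self._state_listeners.append(fn)

    # -- timers ----------------------------------------------------------------

    def timed_goto_state(self, name: str, delay_ms: float) -> TimerEntry:
        if name not in self.defn.states:
            raise TaskError(f"timed_goto_state to unknown state {name!r}")
        handle = self.sched.arm_timer(name, delay_ms, kind=KIND_STATE)
        self._state_timers.append(handle)
        return handle

    def set_event_timer(self, name: str, delay_ms: float) -> TimerEntry:
        if name not in self.defn.events:
            raise TaskError(f"set_event_timer for unknown event {name!r}")
        return self.sched.arm_timer(name, delay_ms, kind=KIND_EVENT)

    def disarm_timer(self, handle: TimerEntry) -> None:
        self.sched.disarm_timer(handle)

    def pause_timer(self, handle: TimerEntry) -> TimerEntry:
        return self.sched.pause_timer(handle)

    def unpause_timer(self, handle: TimerEntry) -> TimerEntry:
        return self.sched.unpause_timer(handle)

    def _disarm_state_timers(self) -> None:
        for handle in self._state_timers:
            if handle.active:
                self.sched.disarm_timer(handle)
        self._state_timers.clear()

    def trigger_event(self, name: str) -> None:
        """Raise an api-source event, delivered this tick after current dispatch."""
        if name not in self.defn.events:
            raise TaskError(f"trigger_event for unknown event {name!r}")
        self.sched.enqueue_event(name, source="api")

    # -- variables and printing -------------------------------------------------

    def set_variable(self, name: str, value) -> None:
        """Externally set a task variable (pre-run or mid-run).

        A variable-change record is logged iff the value differs from the
        task-file default, so data files self-document parameter changes.
        """
        if name not in self.defn.variables:
            raise KeyError(f"undeclared task variable {name!r}")
        self._vars[name] = value
        if value != self.defn.variables[name]:
            self._log("variable_change", self.sched.now, (name, value))

    def get_variable(self, name: str):
        if name not in self.defn.variables:
            raise KeyError(f"undeclared task variable {name!r}")
        return self._vars[name]

    def print(self, text="") -> None:
        """Append a timestamped print record to the session log."""
        if self.phase != "running":
            raise TaskError(f"print on a {self.phase} engine")
        self._log("print", self.sched.now, str(text))
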