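"""Simulated millisecond clock and prioritised event scheduler.

The scheduler is the substrate the task engine runs on.  Time is an integer
millisecond counter starting at 0.  Three classes of pending items exist:

* ``input``  -- edges/threshold crossings from virtual hardware channels,
* ``timer``  -- armed timers (event timers and timed state transitions),
* ``api``    -- events raised directly by task code.

Within a tick, due items are delivered in that class order; within a class,
in FIFO / arming order.  This mirrors the update-loop priority of the real
framework, where hardware interrupts outrank elapsing timers, which outrank
communication with the computer.

Sub-millisecond stimulus times are quantised *upwards* (an edge at 4.2 ms is
delivered at tick 5), so the simulated reaction to any continuous-time input
is late by less than one tick -- the simulated analogue of pulse-timing
errors being "approximately uniformly distributed across 1 ms" on hardware.

Rather than literally iterating every 1 ms tick, ``advance_to`` jumps the
clock straight to the next due item; delivered timestamps and ordering are
identical to a tick-by-tick loop, but a 30-minute session with sparse events
costs microseconds.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass
from typing import Callable, Optional

SOURCE_INPUT = "input"
SOURCE_TIMER = "timer"
SOURCE_API = "api"

KIND_EVENT = "event"
KIND_STATE = "state"


def quantise_ms(t: float) -> int:
    """Quantise a (possibly real-valued) time in ms up to the next tick."""
    return int(math.ceil(t - 1e-9))


@dataclass(eq=False)
class TimerEntry:
    """An armed timer.

    ``kind`` is ``"event"`` (deliver ``target`` as a framework event) or
    ``"state"`` (trigger a transition to state ``target``).  ``remaining``
    is defined only while paused.
    """

    target: str
    kind: str
    expiry: int
    order: int
    paused: bool = False
    remaining: Optional[int] = None
    cancelled: bool = False
    fired: bool = False

    @property
    def active(self) -> bool:
        return not (self.cancelled or self.fired)


@dataclass(frozen=True)
class Dispatched:
    """Record of one delivered item (returned by :meth:`Scheduler.advance_to`)."""

    t: int
    source: str  # input | timer | api
    kind: str  # event | state
    target: str


class Scheduler:
    """Deterministic event queue over a simulated millisecond clock."""

    def __init__(self, dispatch: Optional[Callable[[Dispatched], None]] = None):
        self.now: int = 0
        self.halted: bool = False
        self.dispatch = dispatch
        #: optional set of legal event names; enqueue of others is rejected.
        self.known_events: Optional[set] = None
        self.flush_hook: Optional[Callable[[], None]] = None
        self._inputs: list = []  # heap of (t, seq, name)
        self._api: list = []  # heap of (t, seq, name)
        self._timers: list = []  # heap of (expiry, order, TimerEntry)
        self._seq = itertools.count()

    # -- scheduling -------------------------------------------------------

    def _check_event_name(self, name: str) -> None:
        if self.known_events is not None and name not in self.known_events:
            raise ValueError(f"unknown event name {name!r}")

    def schedule_input(self, t: float, name: str) -> int:
        """Schedule an input-class event at (quantised) time ``t``.

        Returns the integer tick at which the event will be delivered.
        """
        self._check_event_name(name)
        tq = quantise_ms(t)
        if tq < self.now:
            raise ValueError(f"cannot schedule input at {tq} ms before now ({self.now} ms)")
        heapq.heappush(self._inputs, (tq, next(self._seq), name))
        return tq

    def enqueue_event(self, name: str, t: Optional[float] = None, source: str = SOURCE_API) -> int:
        """Append an event to the queue; returns total queue length."""
        self._check_event_name(name)
        tq = self.now if t is None else quantise_ms(t)
        if tq < self.now:
            raise ValueError(f"cannot enqueue event at {tq} ms before now ({self.now} ms)")
        if source == SOURCE_INPUT:
            heapq.heappush(self._inputs, (tq, next(self._seq), name))
        elif source == SOURCE_API:
            heapq.heappush(self._api, (tq, next(self._seq), name))
        elif source == SOURCE_TIMER:
            self.arm_timer(name, tq - self.now, kind=KIND_EVENT)
        else:
            raise ValueError(f"unknown event source {source!r}")
        return len(self._inputs) + len(self._api) + self.n_armed_timers()

    # -- timers -----------------------------------------------------------

    def arm_timer(self, target: str, delay_ms: float, kind: str = KIND_EVENT) -> TimerEntry:
        """Arm a timer firing ``delay_ms`` from now (delay 0 fires this tick,
        after the currently dispatching item completes)."""
        if delay_ms < 0:
            raise ValueError(f"negative timer delay: {delay_ms}")
        if kind not in (KIND_EVENT, KIND_STATE):
            raise ValueError(f"unknown timer kind {kind!r}")
        entry = TimerEntry(
            target=target,
            kind=kind,
            expiry=self.now + quantise_ms(delay_ms),
            order=next(self._seq),
        )
        heapq.heappush(self._timers, (entry.expiry, entry.order, entry))
        return entry

    @staticmethod
    def _check_handle(handle) -> None:
        if not isinstance(handle, TimerEntry):
            raise TypeError(f"not a timer handle: {handle!r}")

    def disarm_timer(self, handle: TimerEntry) -> None:
        """Cancel a timer.  Disarming a fired/cancelled timer is a no-op."""
        self._check_handle(handle)
        handle.cancelled = True

    def pause_timer(self, handle: TimerEntry) -> TimerEntry:
        self._check_handle(handle)
        if not handle.active:
            raise ValueError("cannot pause a timer that is no longer armed")
        if handle.paused:
            raise ValueError("timer is already paused")
        handle.paused = True
        handle.remaining = handle.expiry - self.now
        return handle

    def unpause_timer(self, handle: TimerEntry) -> TimerEntry:
        self._check_handle(handle)
        if not handle.active:
            raise ValueError("cannot unpause a timer that is no longer armed")
        if not handle.paused:
            raise ValueError("timer is not paused")
        handle.paused = False
        handle.expiry = self.now + handle.remaining
        handle.remaining = None
        heapq.heappush(self._timers, (handle.expiry, handle.order, handle))
        return handle

    def disarm_all(self) -> None:
        for _, _, entry in self._timers:
            entry.cancelled = True

    def n_armed_timers(self) -> int:
        return sum(1 for _, _, e in self._timers if e.active and not e.paused)

    def halt(self) -> None:
        """Stop delivering items (set by the engine on run stop/error)."""
        self.halted = True

    # -- the update loop --------------------------------------------------

    def _timer_top(self) -> Optional[TimerEntry]:
        """Next live timer entry, discarding stale heap records."""
        while self._timers:
            expiry, order, entry = self._timers[0]
            if (not entry.active) or entry.paused or entry.expiry != expiry:
                heapq.heappop(self._timers)
                continue
            return entry
        return None

    def _drain_due(self, records: list) -> None:
        """Deliver every item due at the current tick, in priority order.

        Items armed/scheduled *during* dispatch with zero delay are picked up
        within the same tick, after the currently dispatching item.
        """
        dispatched_any = False
        while not self.halted:
            if self._inputs and self._inputs[0][0] <= self.now:
                t, _, name = heapq.heappop(self._inputs)
                item = Dispatched(t, SOURCE_INPUT, KIND_EVENT, name)
            else:
                entry = self._timer_top()
                if entry is not None and entry.expiry <= self.now:
                    heapq.heappop(self._timers)
                    entry.fired = True
                    item = Dispatched(entry.expiry, SOURCE_TIMER, entry.kind, entry.target)
                elif self._api and self._api[0][0] <= self.now:
                    t, _, name = heapq.heappop(self._api)
                    item = Dispatched(t, SOURCE_API, KIND_EVENT, name)
                else:
                    break
            records.append(item)
            dispatched_any = True
            if self.dispatch is not None:
                self.dispatch(item)
        # lowest priority: housekeeping (log flush) after the tick's items.
        if dispatched_any and self.flush_hook is not None:
            self.flush_hook()

    def _next_due_time(self) -> Optional[int]:
        candidates = []
        if self._inputs:
            candidates.append(self._inputs[0][0])
        entry = self._timer_top()
        if entry is not None:
            candidates.append(entry.expiry)
        if self._api:
            candidates.append(self._api[0][0])
        return min(candidates) if candidates else None

    def advance_to(self, t_target: float) -> list:
        """Advance the clock to ``t_target`` ms, delivering all due items.

        Returns the list of :class:`Dispatched` records in delivery order.
        """
        t_target = quantise_ms(t_target)
        if t_target < self.now:
            raise ValueError(f"cannot advance to {t_target} ms: clock already at {self.now} ms")
        records: list = []
        while not self.halted:
            self._drain_due(records)
            if self.halted or self.now >= t_target:
                break
            nxt = self._next_due_time()
            if nxt is None:
                self.now = t_target
            else:
                self.now = min(t_target, max(nxt, self.now + 1))
        return records
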