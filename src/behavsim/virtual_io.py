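"""Virtual hardware channels: the scripted external world.

Digital inputs turn scripted edge times into framework events (rising and/or
falling, with an optional contact-bounce refractory period).  Digital outputs
record a level-change history in simulated time, which tests and analyses
read back instead of an oscilloscope trace.  Analog inputs sample a waveform
function at a fixed rate and emit threshold-crossing events with hysteresis
(a crossing re-arms only after the signal returns past the threshold).

Stimulus generators provide the standard drive signals: square waves (whose
edges deliberately drift against the 1 ms clock when the frequency does not
divide 1 kHz, e.g. 51 Hz) and Poisson edge trains.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .clock import Scheduler, quantise_ms


# -- stimulus generators -----------------------------------------------------

def make_square_wave(freq_hz: float, duration_ms: float) -> List[float]:
    """Edge (toggle) times in ms of a square wave starting low->high at t=0.

    Rising edges fall at k/freq seconds, falling edges at (k+0.5)/freq.
    """
    if freq_hz <= 0 or duration_ms <= 0:
        raise ValueError("frequency and duration must be positive")
    period = 1000.0 / freq_hz
    edges: List[float] = []
    k = 0
    while k * period < duration_ms - 1e-9:
        edges.append(k * period)
        half = k * period + period / 2.0
        if half < duration_ms - 1e-9:
            edges.append(half)
        k += 1
    return edges


def make_poisson_edges(rate_hz: float, duration_ms: float,
                       seed=None, rng: Optional[np.random.Generator] = None) -> List[float]:
    """Edge times (ms) of a Poisson process with the given average rate.

    Inter-edge gaps are i.i.d. exponential with mean 1000/rate ms;
    reproducible under ``seed``.
    """
    if rate_hz <= 0 or duration_ms <= 0:
        raise ValueError("rate and duration must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    mean_gap = 1000.0 / rate_hz
    # draw in blocks until past duration
    edges: List[float] = []
    t = 0.0
    block = max(16, int(duration_ms / mean_gap * 1.2) + 16)
    while t < duration_ms:
        gaps = rng.exponential(mean_gap, size=block)
        for g in gaps:
            t += g
            if t >= duration_ms:
                break
            edges.append(t)
    return edges


def debounce_filter(edges: Sequence[float], debounce_ms: float) -> List[float]:
    """Discard edges within ``debounce_ms`` after each accepted edge."""
    if debounce_ms < 0:
        raise ValueError("debounce must be >= 0")
    accepted: List[float] = []
    last = None
    for t in edges:
        if last is not None and t < last:
            raise ValueError("edge stream must be time-sorted")
        if last is None or t - last >= debounce_ms or debounce_ms == 0:
            accepted.append(t)
            last = t
    return accepted


# -- channels ---------------------------------------------------------------

class DigitalInput:
    """A digital input generating events on rising and/or falling edges."""

    def __init__(self, board: "VirtualBoard", name: str,
                 rising_event: Optional[str] = None,
                 falling_event: Optional[str] = None,
                 debounce: float = 0.0):
        if debounce < 0:
            raise ValueError("debounce must be >= 0")
        self.board = board
        self.name = name
        self.rising_event = rising_event
        self.falling_event = falling_event
        self.debounce = debounce
        self._level = 0
        self._last_accepted: Optional[float] = None
        self._bound = False
        #: accepted (time, level) pairs, for conservation checks.
        self.accepted: List[Tuple[float, int]] = []

    def _edge(self, t: float, level: int) -> Optional[int]:
        """Apply the debounce filter and (if accepted) schedule the event.

        Returns the delivery tick, or None if the edge was debounced away.
        """
        if self._last_accepted is not None and self.debounce > 0 \
                and t - self._last_accepted < self.debounce:
            return None
        self._last_accepted = t
        self._level = level
        self.accepted.append((t, level))
        event = self.rising_event if level else self.falling_event
        if event is not None:
            return self.board.sched.schedule_input(t, event)
        return None

    def play(self, edge_times: Iterable[float], initial_level: int = 0) -> int:
        """Bind a scripted edge stream to this input.

        ``edge_times`` are toggle times in ms (real-valued allowed; quantised
        up to the next tick on delivery), starting from ``initial_level``.
        Returns the number of accepted edges.  An input can be bound once.
        """
        if self._bound:
            raise RuntimeError(f"digital input {self.name!r} is already bound")
        self._bound = True
        level = initial_level
        prev = -math.inf
        n0 = len(self.accepted)
        for t in edge_times:
            if t < prev:
                raise ValueError("edge times must be sorted")
            prev = t
            level = 1 - level
            self._edge(t, level)
        return len(self.accepted) - n0

    def inject(self, t: float, edge: str = "rising") -> Optional[int]:
        """Inject a single edge at runtime (used by closed-loop agents)."""
        if edge not in ("rising", "falling"):
            raise ValueError(f"edge must be 'rising' or 'falling', got {edge!r}")
        return self._edge(t, 1 if edge == "rising" else 0)


class DigitalOutput:
    """A digital output recording its level-change history in simulated time."""

    def __init__(self, board: "VirtualBoard", name: str):
        self.board = board
        self.name = name
        self._level = 0
        #: list of (t_ms, level) level *changes*; initial level is 0.
        self.history: List[Tuple[int, int]] = []

    @property
    def level(self) -> int:
        return self._level

    def set(self, level) -> None:
        level = 1 if level else 0
        if level != self._level:  # idempotent sets recorded once
            self._level = level
            self.history.append((self.board.sched.now, level))

    def on(self) -> None:
        self.set(1)

    def off(self) -> None:
        self.set(0)

    def pulses(self) -> List[Tuple[int, int]]:
        """Closed (t_on, t_off) pairs from the history; a trailing unclosed
        pulse is omitted."""
        out = []
        t_on = None
        for t, level in self.history:
            if level == 1:
                t_on = t
            elif t_on is not None:
                out.append((t_on, t))
                t_on = None
        return out


class AnalogInput:
    """An analog input: fixed-rate sampling plus threshold events.

    Threshold semantics are strict crossings with state memory: an
    upper-threshold event fires at the first sample strictly above the
    threshold after the signal was at-or-below it (symmetrically for the
    lower threshold), so a signal sitting beyond a threshold does not
    re-trigger.
    """

    def __init__(self, board: "VirtualBoard", name: str, sample_rate: float,
                 upper_threshold: Optional[float] = None,
                 rising_event: Optional[str] = None,
                 lower_threshold: Optional[float] = None,
                 falling_event: Optional[str] = None,
                 scale: float = 1.0):
        if sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for thr in (upper_threshold, lower_threshold):
            if thr is not None and not math.isfinite(thr):
                raise ValueError("thresholds must be finite")
        self.board = board
        self.name = name
        self.sample_rate = sample_rate
        self.upper_threshold = upper_threshold
        self.rising_event = rising_event
        self.lower_threshold = lower_threshold
        self.falling_event = falling_event
        self.scale = scale
        self._bound = False
        self.sample_times: np.ndarray = np.empty(0, dtype=np.int32)
        self.sample_values: np.ndarray = np.empty(0, dtype=np.int32)

    def play(self, waveform: Callable[[float], float], duration_ms: float) -> int:
        """Sample ``waveform(t_ms)`` for ``duration_ms``; schedule threshold
        events; record integer samples.  Returns the number of samples."""
        if duration_ms <= 0:
            raise ValueError("duration must be positive")
        if self._bound:
            raise RuntimeError(f"analog input {self.name!r} is already bound")
        self._bound = True
        dt = 1000.0 / self.sample_rate
        n = int(math.floor(duration_ms / dt - 1e-9)) + 1
        if (n - 1) * dt >= duration_ms - 1e-9:
            n -= 1
        times = np.arange(n) * dt
        raw = np.array([float(waveform(t)) for t in times])
        values = np.rint(raw * self.scale).astype(np.int32)
        self.sample_times = np.array([quantise_ms(t) for t in times], dtype=np.int32)
        self.sample_values = values
        above = False  # armed for upper crossing when False
        below = False
        for t, val in zip(times, raw):
            if self.upper_threshold is not None:
                if not above and val > self.upper_threshold:
                    above = True
                    if self.rising_event is not None:
                        self.board.sched.schedule_input(t, self.rising_event)
                elif above and val <= self.upper_threshold:
                    above = False
            if self.lower_threshold is not None:
                if not below and val < self.lower_threshold:
                    below = True
                    if self.falling_event is not None:
                        self.board.sched.schedule_input(t, self.falling_event)
                elif below and val >= self.lower_threshold:
                    below = False
        return n


def apply_stimulus_script(board: "VirtualBoard", script: dict,
                          duration_ms: float) -> None:
    """Bind a declarative stimulus script to a board's input channels.

    ``script`` maps channel name -> one spec (times in ms):

    * ``{"edges": [t0, t1, ...]}`` -- explicit toggle times;
    * ``{"square_wave": {"freq_hz": f, "duration_ms": d?}}``;
    * ``{"poisson": {"rate_hz": r, "seed": s, "duration_ms": d?}}``;
    * ``{"sine": {"freq_hz": f, "amplitude": a, "offset": o?}}`` -- for an
      analog channel, sampled at its configured rate.

    ``duration_ms`` is the default duration where a spec omits it.  Loadable
    from YAML/JSON via :func:`load_stimulus_script`.
    """
    for channel_name, spec in script.items():
        channel = board[channel_name]
        if len(spec) != 1:
            raise ValueError(f"channel {channel_name!r}: expected exactly one "
                             f"generator spec, got {sorted(spec)}")
        (kind, cfg), = spec.items()
        if kind == "edges":
            channel.play(list(cfg))
        elif kind == "square_wave":
            channel.play(make_square_wave(cfg["freq_hz"],
                                          cfg.get("duration_ms", duration_ms)))
        elif kind == "poisson":
            channel.play(make_poisson_edges(cfg["rate_hz"],
                                            cfg.get("duration_ms", duration_ms),
                                            seed=cfg.get("seed", 0)))
        elif kind == "sine":
            freq, amp = cfg["freq_hz"], cfg["amplitude"]
            offset = cfg.get("offset", 0.0)
            channel.play(lambda t: offset + amp * math.sin(2 * math.pi * freq * t / 1000.0),
                         cfg.get("duration_ms", duration_ms))
        else:
            raise ValueError(f"channel {channel_name!r}: unknown generator "
                             f"kind {kind!r}")


def load_stimulus_script(path) -> dict:
    """Read a stimulus script from a YAML (or JSON) file."""
    import yaml

    with open(str(path), encoding="utf-8") as fh:
        script = yaml.safe_load(fh)
    if not isinstance(script, dict):
        raise ValueError(f"stimulus script {path} must map channel names to specs")
    return script


class VirtualBoard:
    """Container of named virtual channels bound to one scheduler.

    Channels are exposed as attributes/items, so task code reads naturally:
    ``run.hw.LED.on()``, ``run.hw['poke_3']``.
    """

    def __init__(self, scheduler: Scheduler):
        self.sched = scheduler
        self._channels: dict = {}

    def _register(self, name: str, channel):
        if name in self._channels:
            raise ValueError(f"channel name {name!r} already in use")
        self._channels[name] = channel
        return channel

    def digital_input(self, name: str, rising_event: Optional[str] = None,
                      falling_event: Optional[str] = None,
                      debounce: float = 0.0) -> DigitalInput:
        return self._register(name, DigitalInput(self, name, rising_event,
                                                 falling_event, debounce))

    def digital_output(self, name: str) -> DigitalOutput:
        return self._register(name, DigitalOutput(self, name))

    def analog_input(self, name: str, sample_rate: float, **kwargs) -> AnalogInput:
        return self._register(name, AnalogInput(self, name, sample_rate, **kwargs))

    def __getattr__(self, name):
        try:
            return self.__dict__["_channels"][name]
        except KeyError:
            raise AttributeError(f"no channel named {name!r}") from None

    def __getitem__(self, name):
        try:
            return self._channels[name]
        except KeyError:
            raise KeyError(f"no channel named {name!r}") from None

    def __contains__(self, name) -> bool:
        return name in self._channels

    @property
    def channels(self) -> dict:
        return dict(self._channels)

    def analog_channels(self) -> list:
        return [ch for ch in self._channels.values() if isinstance(ch, AnalogInput)]
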