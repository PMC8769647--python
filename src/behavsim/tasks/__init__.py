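"""Fixture task library: worked-example, validation, and behavioural tasks.

Each fixture bundles a task definition, the virtual channels it needs, and a
default drive (stimulus script or closed-loop agent).  ``run_fixture`` builds
and runs one session; the experiment runner and CLI resolve fixtures by name
through ``REGISTRY``.
"""

from __future__ import annotations

import inspect
import sys
from dataclasses import dataclass
from typing import Optional

from ..clock import Scheduler
from ..engine import Engine, TaskDefinition
from ..session_log import (SessionHeader, SessionWriter, analog_path,
                           build_id_maps, task_file_hash, write_analog)
from ..virtual_io import VirtualBoard
from ._base import Fixture
from .button import ButtonLedFixture, button_led_task
from .five_choice import (STAGES, AgentSpec, FiveChoiceAgent, FiveChoiceFixture,
                          FiveChoiceStage, TrialOutcome, classify_outcome,
                          criteria_met, five_choice_task, metrics_from_session,
                          probe_trial, session_metrics, stage_controller,
                          wire_five_choice_board)
from .go_nogo import GoNogoAgent, GoNogoFixture, go_nogo_task, wire_go_nogo_board
from .validation import (InputFollowerFixture, PoissonEventsFixture,
                         TriggeredPulsesFixture, input_follower_task,
                         poisson_events_task, triggered_pulses_task)

REGISTRY = {
    cls.name: cls
    for cls in (ButtonLedFixture, InputFollowerFixture, TriggeredPulsesFixture,
                PoissonEventsFixture, FiveChoiceFixture, GoNogoFixture)
}


def list_fixtures() -> dict:
    """Fixture name -> one-line description."""
    return {name: cls.description for name, cls in REGISTRY.items()}


def get_fixture(name: str) -> Fixture:
    try:
        return REGISTRY[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r} "
                       f"(available: {sorted(REGISTRY)})") from None


def fixture_source(fixture: Fixture) -> str:
    """Source text of the module defining the fixture's task (hashed and
    archived alongside session data)."""
    return inspect.getsource(sys.modules[type(fixture).__module__])


@dataclass
class PreparedRun:
    """A session ready to execute: call :meth:`run`."""

    fixture: Fixture
    engine: Engine
    board: VirtualBoard
    scheduler: Scheduler
    params: dict
    session_path: Optional[str] = None

    def run(self) -> dict:
        summary = self.engine.run(self.params["duration_ms"])
        if self.session_path is not None:
            for ch in self.board.analog_channels():
                write_analog(analog_path(self.session_path, ch.name),
                             ch.sample_times, ch.sample_values)
        return summary


def prepare_run(fixture_name: str, *, seed: int = 0, params: Optional[dict] = None,
                session_path=None, subject: str = "sim1",
                experiment: str = "adhoc", when: str = "1970-01-01T00:00:00",
                variables: Optional[dict] = None,
                overwrite: bool = False) -> PreparedRun:
    """Build scheduler, board, engine and drive for one fixture session.

    ``variables`` are external pre-run overrides of declared task variables
    (logged as variable-change records when they differ from defaults).
    ``when`` is the header start time; pass a fixed string for byte-identical
    reruns.
    """
    fixture = get_fixture(fixture_name)
    full_params = dict(fixture.default_params)
    full_params.setdefault("duration_ms", fixture.default_duration_ms)
    if params:
        unknown = set(params) - set(full_params)
        if unknown:
            raise ValueError(f"unknown parameters for fixture {fixture_name!r}: "
                             f"{sorted(unknown)}")
        full_params.update(params)

    scheduler = Scheduler()
    board = VirtualBoard(scheduler)
    defn = fixture.build(board, full_params)

    writer = None
    if session_path is not None:
        header = SessionHeader(
            experiment=experiment,
            task_name=defn.name,
            task_hash=task_file_hash(fixture_source(fixture)),
            subject=subject,
            start_time=when,
            seed=seed,
        )
        state_ids, event_ids = build_id_maps(defn.states, defn.events)
        writer = SessionWriter(session_path, header, state_ids, event_ids,
                               overwrite=overwrite)

    engine = Engine(defn, scheduler, board=board, writer=writer, seed=seed)
    if variables:
        for name, value in variables.items():
            engine.set_variable(name, value)
    fixture.drive(engine, full_params, seed)
    return PreparedRun(fixture, engine, board, scheduler, full_params,
                       session_path=None if session_path is None else str(session_path))


def run_fixture(fixture_name: str, **kwargs) -> PreparedRun:
    """Prepare and run one fixture session; returns the PreparedRun (its
    ``engine`` carries the in-memory log and final variables)."""
    prepared = prepare_run(fixture_name, **kwargs)
    prepared.run()
    return prepared


__all__ = [
    "AgentSpec", "Fixture", "FiveChoiceAgent", "FiveChoiceFixture",
    "FiveChoiceStage", "GoNogoAgent", "PreparedRun", "REGISTRY", "STAGES",
    "TrialOutcome", "button_led_task", "classify_outcome", "criteria_met",
    "five_choice_task", "fixture_source", "get_fixture", "go_nogo_task",
    "input_follower_task", "list_fixtures", "metrics_from_session",
    "poisson_events_task", "prepare_run", "probe_trial", "run_fixture",
    "session_metrics", "stage_controller", "triggered_pulses_task",
    "wire_five_choice_board", "wire_go_nogo_board",
]
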