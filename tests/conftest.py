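"""Shared fixtures: tiny tasks and session-writing helpers."""

import pytest

from behavsim import (Engine, Scheduler, SessionHeader, SessionWriter,
                      TaskDefinition, VirtualBoard, build_id_maps)


def make_recorder_task(states=("a", "b"), events=("x", "y"), initial="a",
                       all_states=None, variables=None):
    """A task whose behaviour functions append (state, event) to
    ``run.scratch['trace']`` and otherwise do nothing."""

    def behaviour_for(state):
        def fn(run, event):
            run.scratch.setdefault("trace", []).append((state, event))
        return fn

    return TaskDefinition(
        name="recorder",
        states=states,
        events=events,
        initial_state=initial,
        behaviour={s: behaviour_for(s) for s in states},
        all_states=all_states,
        variables=dict(variables or {}),
    )


@pytest.fixture
def sched():
    return Scheduler()


@pytest.fixture
def engine_factory(sched):
    def build(defn=None, board=None, writer=None, seed=0, **task_kwargs):
        if defn is None:
            defn = make_recorder_task(**task_kwargs)
        return Engine(defn, sched, board=board, writer=writer, seed=seed)
    return build


@pytest.fixture
def session_writer_factory(tmp_path):
    counter = [0]

    def build(states=("a", "b"), events=("x", "y"), **header_kwargs):
        counter[0] += 1
        header = SessionHeader(
            experiment=header_kwargs.get("experiment", "test_exp"),
            task_name=header_kwargs.get("task_name", "test_task"),
            task_hash=header_kwargs.get("task_hash", "00000000"),
            subject=header_kwargs.get("subject", "m1"),
            start_time=header_kwargs.get("start_time", "1970-01-01T00:00:00"),
            seed=header_kwargs.get("seed", 0),
        )
        state_ids, event_ids = build_id_maps(states, events)
        path = tmp_path / f"session_{counter[0]}.txt"
        return SessionWriter(path, header, state_ids, event_ids), path

    return build
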