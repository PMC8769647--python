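"""Task-engine semantics: validation, entry/exit, all_states, variables,
timed transitions, error trapping, run lifecycle."""

import pytest

from behavsim import Engine, Scheduler, TaskDefinition, TaskError, validate_task
from behavsim.tasks import button_led_task

from conftest import make_recorder_task


# -- validation ----------------------------------------------------------------

def test_worked_example_task_is_valid():
    assert validate_task(button_led_task()) == []


@pytest.mark.parametrize("mutation, fragment", [
    (dict(initial="nope"), "initial_state"),
    (dict(states=("a", "b"), events=("a",)), "both state and event"),
    (dict(states=("a", "a")), "duplicate state"),
    (dict(events=("entry",)), "reserved"),
    (dict(states=("a", "bad name")), "whitespace"),
])
def test_validation_reports_each_invariant_violation(mutation, fragment):
    defn = make_recorder_task(**mutation)
    problems = validate_task(defn)
    assert any(fragment in p for p in problems)


def test_missing_behaviour_function_reported():
    defn = make_recorder_task()
    behaviour = dict(defn.behaviour)
    del behaviour["b"]
    defn = TaskDefinition(defn.name, defn.states, defn.events, defn.initial_state,
                          behaviour, variables=defn.variables)
    assert any("no behaviour" in p for p in validate_task(defn))


# -- run lifecycle -------------------------------------------------------------

def test_start_dispatches_entry_to_initial_state_at_t0(engine_factory):
    eng = engine_factory()
    eng.start_run()
    assert eng.scratch["trace"] == [("a", "entry")]
    assert eng.current_state == "a"
    assert [r for r in eng.log if r.kind == "state_entry"] \
        == [("state_entry", 0, "a")]


def test_double_start_and_double_stop_are_diagnosed(engine_factory):
    eng = engine_factory()
    eng.start_run()
    with pytest.raises(TaskError):
        eng.start_run()
    eng.stop_run()
    with pytest.raises(TaskError):
        eng.stop_run()


def test_stop_disarms_timers_so_nothing_follows_the_end_record(engine_factory, sched):
    eng = engine_factory()
    eng.start_run()
    eng.set_event_timer("x", 50)
    eng.stop_run()
    sched.halted = False  # even if time were pushed on, nothing is delivered
    sched.advance_to(100)
    kinds = [r.kind for r in eng.log]
    assert kinds[-1] == "end"
    assert "event" not in kinds


def test_chained_entry_transitions_log_all_states_in_order_at_one_tick():
    sched = Scheduler()
    states = ("A", "B", "C")

    def make(nxt):
        def fn(run, event):
            if event == "entry" and nxt is not None:
                run.goto_state(nxt)
        return fn

    defn = TaskDefinition("chain", states, ("x",), "A",
                          {"A": make("B"), "B": make("C"), "C": make(None)})
    eng = Engine(defn, sched)
    eng.start_run()
    assert [(r.payload, r.t) for r in eng.log if r.kind == "state_entry"] \
        == [("A", 0), ("B", 0), ("C", 0)]


def test_self_transition_runs_exit_then_entry(engine_factory):
    eng = engine_factory()
    eng.start_run()
    eng.goto_state("a")
    assert eng.scratch["trace"] == [("a", "entry"), ("a", "exit"), ("a", "entry")]
    assert sum(1 for r in eng.log if r.kind == "state_entry") == 2


def test_goto_state_from_exit_handler_errors_the_run():
    sched = Scheduler()

    def a(run, event):
        if event in ("x", "exit"):  # the exit-time goto is the recursion guard case
            run.goto_state("b")

    defn = TaskDefinition("bad_exit", ("a", "b"), ("x",), "a",
                          {"a": a, "b": lambda run, event: None})
    eng = Engine(defn, sched)
    eng.start_run()
    sched.enqueue_event("x", source="input")
    sched.advance_to(1)
    assert eng.phase == "errored"
    assert any("exit handler" in r.payload for r in eng.log if r.kind == "error")


# -- event processing ----------------------------------------------------------

def test_event_with_no_behaviour_branch_is_still_logged(engine_factory, sched):
    eng = engine_factory()
    eng.start_run()
    sched.enqueue_event("y", source="input")
    sched.advance_to(5)
    assert ("event", 0, "y") in eng.log
    assert eng.current_state == "a"


def test_all_states_sees_event_first_and_can_suppress():
    sched = Scheduler()
    calls = []

    def all_states(run, event):
        calls.append(("all", event))
        return event == "x"  # suppress x from the state behaviour

    def a(run, event):
        calls.append(("state", event))

    defn = TaskDefinition("sup", ("a",), ("x", "y"), "a", {"a": a},
                          all_states=all_states)
    eng = Engine(defn, sched)
    eng.start_run()
    sched.enqueue_event("x", source="input")
    sched.enqueue_event("y", source="input")
    sched.advance_to(1)
    assert ("all", "x") in calls and ("state", "x") not in calls
    assert calls.index(("all", "y")) < calls.index(("state", "y"))
    # entry/exit go only to the state behaviour
    assert ("all", "entry") not in calls and ("state", "entry") in calls


def test_exception_in_behaviour_logs_traceback_and_errors_run():
    sched = Scheduler()

    def a(run, event):
        if event == "x":
            raise RuntimeError("broken handler")

    defn = TaskDefinition("boom", ("a",), ("x",), "a", {"a": a})
    eng = Engine(defn, sched)
    eng.start_run()
    sched.enqueue_event("x", source="input")
    sched.advance_to(1)
    assert eng.phase == "errored"
    err = [r for r in eng.log if r.kind == "error"]
    assert len(err) == 1 and "broken handler" in err[0].payload \
        and "RuntimeError" in err[0].payload
    assert eng.log[-1].kind == "end"


def test_reserved_and_unknown_events_cannot_be_raised(engine_factory):
    eng = engine_factory()
    eng.start_run()
    with pytest.raises(TaskError, match="reserved"):
        eng.process_event("entry")
    with pytest.raises(TaskError, match="unknown"):
        eng.process_event("not_declared")
    with pytest.raises(TaskError, match="unknown"):
        eng.trigger_event("not_declared")


# -- timed transitions ---------------------------------------------------------

def test_timed_goto_state_fires_after_exact_delay():
    sched = Scheduler()

    def a(run, event):
        if event == "entry":
            run.timed_goto_state("b", 1000)

    defn = TaskDefinition("tg", ("a", "b"), ("x",), "a",
                          {"a": a, "b": lambda run, event: None})
    eng = Engine(defn, sched)
    eng.start_run()
    sched.advance_to(5000)
    assert [(r.payload, r.t) for r in eng.log if r.kind == "state_entry"] \
        == [("a", 0), ("b", 1000)]


def test_manual_transition_cancels_pending_timed_goto():
    sched = Scheduler()

    def a(run, event):
        if event == "entry":
            run.timed_goto_state("b", 100)
        elif event == "x":
            run.goto_state("c")

    defn = TaskDefinition("cancel", ("a", "b", "c"), ("x",), "a",
                          {"a": a, "b": lambda r, e: None, "c": lambda r, e: None})
    eng = Engine(defn, sched)
    eng.start_run()
    sched.enqueue_event("x", t=50, source="input")
    sched.advance_to(500)
    entries = [r.payload for r in eng.log if r.kind == "state_entry"]
    assert entries == ["a", "c"]  # the timed a->b never fires
    assert eng.current_state == "c"


def test_timed_goto_to_unknown_state_is_rejected_at_arming(engine_factory):
    eng = engine_factory()
    eng.start_run()
    with pytest.raises(TaskError, match="unknown state"):
        eng.timed_goto_state("nowhere", 10)


def test_zero_delay_timed_goto_transitions_within_the_same_tick():
    sched = Scheduler()

    def a(run, event):
        if event == "entry":
            run.timed_goto_state("b", 0)

    defn = TaskDefinition("z", ("a", "b"), ("x",), "a",
                          {"a": a, "b": lambda r, e: None})
    eng = Engine(defn, sched)
    eng.start_run()
    sched.advance_to(0)
    assert [(r.payload, r.t) for r in eng.log if r.kind == "state_entry"] \
        == [("a", 0), ("b", 0)]


# -- variables and prints ------------------------------------------------------

def test_setting_a_variable_away_from_default_is_logged_once(engine_factory):
    eng = engine_factory(variables={"threshold": 3})
    eng.set_variable("threshold", 5)
    assert [r for r in eng.log if r.kind == "variable_change"] \
        == [("variable_change", 0, ("threshold", 5))]
    assert eng.get_variable("threshold") == 5


def test_setting_a_variable_to_its_default_is_not_logged(engine_factory):
    eng = engine_factory(variables={"threshold": 3})
    eng.set_variable("threshold", 3)
    assert [r for r in eng.log if r.kind == "variable_change"] == []


def test_undeclared_variables_are_diagnosed(engine_factory):
    eng = engine_factory(variables={"threshold": 3})
    with pytest.raises(KeyError, match="undeclared"):
        eng.set_variable("nope", 1)
    with pytest.raises(KeyError, match="undeclared"):
        eng.get_variable("nope")
    eng.start_run()
    with pytest.raises(AttributeError, match="undeclared"):
        eng.v.nope = 2


def test_in_task_variable_writes_are_not_logged_as_changes():
    sched = Scheduler()

    def a(run, event):
        if event == "entry":
            run.v.counter += 1

    defn = TaskDefinition("vars", ("a",), ("x",), "a", {"a": a},
                          variables={"counter": 0})
    eng = Engine(defn, sched)
    eng.start_run()
    assert eng.v.counter == 1
    assert [r for r in eng.log if r.kind == "variable_change"] == []


def test_print_records_carry_the_simulated_timestamp():
    sched = Scheduler()

    def a(run, event):
        if event == "x":
            run.print("hello trial")
        elif event == "y":
            run.print("")

    defn = TaskDefinition("pr", ("a",), ("x", "y"), "a", {"a": a})
    eng = Engine(defn, sched)
    eng.start_run()
    sched.enqueue_event("x", t=1234, source="input")
    sched.enqueue_event("y", t=2000, source="input")
    sched.advance_to(3000)
    assert [r for r in eng.log if r.kind == "print"] \
        == [("print", 1234, "hello trial"), ("print", 2000, "")]


def test_event_timestamps_are_non_decreasing_and_every_event_logged_once(engine_factory, sched):
    import numpy as np

    eng = engine_factory()
    eng.start_run()
    rng = np.random.default_rng(1)
    times = rng.integers(0, 500, size=200)
    for t in times:
        sched.enqueue_event("x", t=int(t), source="input")
    sched.advance_to(600)
    logged = [r.t for r in eng.log if r.kind == "event"]
    assert len(logged) == 200
    assert logged == sorted(logged)
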