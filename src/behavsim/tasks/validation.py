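"""Timing-validation fixtures, re-expressed in simulated time.

* ``input-follower`` -- sets a digital output to match a digital input; with
  a 51 Hz square-wave drive the input edges drift against the 1 ms clock, so
  the output tracks the input with a sub-tick quantisation lag.
* ``triggered-pulses`` -- emits a 10 ms output pulse on every rising input
  edge; in simulated time every pulse is exactly 10 ms.
* ``poisson-events`` -- counts framework events generated by two digital
  inputs driven by independent Poisson edge processes (200 Hz each by
  default), the standard high-load condition.
"""

from __future__ import annotations

from ..engine import TaskDefinition
from ..virtual_io import VirtualBoard, make_poisson_edges, make_square_wave
from ._base import Fixture


def input_follower_task() -> TaskDefinition:
    def follow(run, event):
        if event == "input_on":
            run.hw.output.on()
        elif event == "input_off":
            run.hw.output.off()

    return TaskDefinition(
        name="input_follower",
        states=("follow",),
        events=("input_on", "input_off"),
        initial_state="follow",
        behaviour={"follow": follow},
    )


def triggered_pulses_task() -> TaskDefinition:
    def idle(run, event):
        if event == "input_rise":
            run.goto_state("pulse_on")

    def pulse_on(run, event):
        if event == "entry":
            run.hw.output.on()
            run.timed_goto_state("idle", run.v.pulse_ms)
        elif event == "exit":
            run.hw.output.off()

    return TaskDefinition(
        name="triggered_pulses",
        states=("idle", "pulse_on"),
        events=("input_rise",),
        initial_state="idle",
        behaviour={"idle": idle, "pulse_on": pulse_on},
        variables={"pulse_ms": 10},
    )


def poisson_events_task() -> TaskDefinition:
    def count(run, event):
        if event == "ch1":
            run.v.n1 += 1
        elif event == "ch2":
            run.v.n2 += 1

    return TaskDefinition(
        name="poisson_events",
        states=("count",),
        events=("ch1", "ch2"),
        initial_state="count",
        behaviour={"count": count},
        variables={"n1": 0, "n2": 0},
    )


class InputFollowerFixture(Fixture):
    name = "input-follower"
    description = "digital output mirrors a square-wave digital input"
    default_params = {"freq_hz": 51.0}
    default_duration_ms = 50_000

    def build(self, board: VirtualBoard, params: dict) -> TaskDefinition:
        board.digital_input("input", rising_event="input_on", falling_event="input_off")
        board.digital_output("output")
        return input_follower_task()

    def drive(self, engine, params: dict, seed: int) -> None:
        edges = make_square_wave(params["freq_hz"], params["duration_ms"])
        engine.board["input"].play(edges)


class TriggeredPulsesFixture(Fixture):
    name = "triggered-pulses"
    description = "10 ms output pulse on every rising edge of a square-wave input"
    default_params = {"freq_hz": 51.0}
    default_duration_ms = 50_000

    def build(self, board: VirtualBoard, params: dict) -> TaskDefinition:
        board.digital_input("input", rising_event="input_rise")
        board.digital_output("output")
        return triggered_pulses_task()

    def drive(self, engine, params: dict, seed: int) -> None:
        edges = make_square_wave(params["freq_hz"], params["duration_ms"])
        engine.board["input"].play(edges)


class PoissonEventsFixture(Fixture):
    name = "poisson-events"
    description = "two inputs generating events as independent Poisson processes"
    default_params = {"rate_hz": 200.0}
    default_duration_ms = 100_000

    def build(self, board: VirtualBoard, params: dict) -> TaskDefinition:
        # every edge (rising or falling) generates the channel's event
        board.digital_input("in1", rising_event="ch1", falling_event="ch1")
        board.digital_input("in2", rising_event="ch2", falling_event="ch2")
        return poisson_events_task()

    def drive(self, engine, params: dict, seed: int) -> None:
        duration = params["duration_ms"]
        rate = params["rate_hz"]
        engine.board["in1"].play(make_poisson_edges(rate, duration, seed=[seed, 1]))
        engine.board["in2"].play(make_poisson_edges(rate, duration, seed=[seed, 2]))
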