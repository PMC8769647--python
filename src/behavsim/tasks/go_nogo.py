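"""Simplified Go/NoGo lick task for head-fixed sensory discrimination.

Each trial presents a pole at one of two positions: anterior ("Go": licking
in the response window delivers a water reward) or posterior ("NoGo": licking
triggers a timeout).  The lick/withhold window starts when the pole is
withdrawn.  Outcomes: Go+lick = hit, Go+no-lick = miss, NoGo+lick = false
alarm, NoGo+no-lick = correct rejection.

The original study prints no numeric trial parameters, so the window lengths
and timeout are configurable task variables with documented defaults
(ITI 3 s, stimulus 1 s, response window 1.5 s, timeout 2 s, drink 1 s).
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from ..engine import TaskDefinition
from ..virtual_io import VirtualBoard
from ._base import Fixture

GO_NOGO_OUTCOMES = ("hit", "miss", "false_alarm", "correct_rejection")

DEFAULTS = {
    "p_go": 0.5,
    "iti_ms": 3000,
    "stim_ms": 1000,
    "resp_ms": 1500,
    "timeout_ms": 2000,
    "drink_ms": 1000,
    "reward_ul": 5,
    "session_ms": 30 * 60_000,
}


def _record_trial(run, outcome: str) -> None:
    run.v.n_trials += 1
    run.v[f"n_{outcome}"] += 1
    run.v.trial_open = False
    kind = "go" if run.v.is_go else "nogo"
    run.print(f"trial {run.v.n_trials} {kind} {outcome}")


def go_nogo_task(params: Optional[Dict] = None) -> TaskDefinition:
    cfg = dict(DEFAULTS)
    if params:
        unknown = set(params) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown go/nogo parameters: {sorted(unknown)}")
        cfg.update(params)

    def init(run, event):
        if event == "entry":
            run.set_event_timer("session_timeout", run.v.session_ms)
            run.goto_state("iti")

    def iti(run, event):
        if event == "entry":
            if run.v.trial_open:  # response window elapsed without a lick
                _record_trial(run, "miss" if run.v.is_go else "correct_rejection")
            run.timed_goto_state("stimulus", run.v.iti_ms)

    def stimulus(run, event):
        # licks during the pole presentation have no programmed consequence
        if event == "entry":
            run.v.is_go = bool(run.rng.random() < run.v.p_go)
            run.v.trial_open = True
            run.hw["pole_go" if run.v.is_go else "pole_nogo"].on()
            run.timed_goto_state("response", run.v.stim_ms)
        elif event == "exit":  # pole withdrawn; lick/withhold window starts
            run.hw["pole_go" if run.v.is_go else "pole_nogo"].off()

    def response(run, event):
        if event == "entry":
            run.timed_goto_state("iti", run.v.resp_ms)
        elif event == "lick":
            if run.v.is_go:
                _record_trial(run, "hit")
                run.goto_state("reward")
            else:
                _record_trial(run, "false_alarm")
                run.goto_state("timeout")

    def reward(run, event):
        if event == "entry":
            run.hw.water.on()
            run.print(f"reward {run.v.reward_ul}")
            run.timed_goto_state("iti", run.v.drink_ms)
        elif event == "exit":
            run.hw.water.off()

    def timeout(run, event):
        if event == "entry":
            run.timed_goto_state("iti", run.v.timeout_ms)

    def all_states(run, event):
        if event == "session_timeout":
            run.print("session complete")
            run.stop()
            return True

    variables = dict(cfg)
    variables.update({
        "n_trials": 0, "n_hit": 0, "n_miss": 0, "n_false_alarm": 0,
        "n_correct_rejection": 0, "is_go": False, "trial_open": False,
    })
    return TaskDefinition(
        name="go_nogo",
        states=("init", "iti", "stimulus", "response", "reward", "timeout"),
        events=("lick", "session_timeout"),
        initial_state="init",
        behaviour={"init": init, "iti": iti, "stimulus": stimulus,
                   "response": response, "reward": reward, "timeout": timeout},
        all_states=all_states,
        variables=variables,
    )


def wire_go_nogo_board(board: VirtualBoard) -> None:
    board.digital_input("lickometer", rising_event="lick")
    board.digital_output("pole_go")
    board.digital_output("pole_nogo")
    board.digital_output("water")


class GoNogoAgent:
    """Licks in the response window with trial-type-dependent probability."""

    def __init__(self, board: VirtualBoard, p_lick_go: float = 0.8,
                 p_lick_nogo: float = 0.3, seed=0):
        self.board = board
        self.p_lick_go = p_lick_go
        self.p_lick_nogo = p_lick_nogo
        self.rng = np.random.default_rng(seed)
        self.engine = None

    def attach(self, engine) -> None:
        self.engine = engine
        engine.add_state_listener(self.on_state)

    def on_state(self, state: str, t: int) -> None:
        if state != "response":
            return
        run = self.engine
        p = self.p_lick_go if run.v.is_go else self.p_lick_nogo
        if self.rng.random() < p:
            latency = self.rng.uniform(100, run.v.resp_ms - 100)
            self.board["lickometer"].inject(t + latency, "rising")


class GoNogoFixture(Fixture):
    name = "go-nogo"
    description = "go/nogo pole-position lick task with a stochastic licker"
    default_params = {"p_go": 0.5, "p_lick_go": 0.8, "p_lick_nogo": 0.3}
    default_duration_ms = 10 * 60_000

    def build(self, board: VirtualBoard, params: dict) -> TaskDefinition:
        wire_go_nogo_board(board)
        return go_nogo_task({"p_go": params["p_go"],
                             "session_ms": params["duration_ms"]})

    def drive(self, engine, params: dict, seed: int) -> None:
        agent = GoNogoAgent(engine.board, params["p_lick_go"],
                            params["p_lick_nogo"], seed=[seed, 1])
        agent.attach(engine)
        engine.scratch["agent"] = agent
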