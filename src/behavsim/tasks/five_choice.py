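"""5-choice serial reaction time task (5-CSRTT) fixture.

Trial structure: an inter-trial interval (ITI, initiated when the subject
exits the reward receptacle or a timeout ends) is followed by illumination of
one pseudorandomly chosen hole of the 5-choice wall for the stimulus duration
(SD), then a 2 s hold window.  A poke in the lit port during SD or hold is a
*correct* response (receptacle light + 20 ul milk reward); a poke in any hole
during the ITI is *premature*; a poke in a non-illuminated hole during SD or
hold is *incorrect*; no poke at all is an *omission*.  Non-rewarded outcomes
end in a 5 s timeout with the house light off.  Sessions stop automatically
after 30 min.  One print line per trial records trial number, outcome and
port.

Training follows staged difficulty (S1..S5) with stage advancement when
criteria are met on two consecutive days, plus single-day challenge protocols
(C1..C5) probing impulsivity (longer or variable ITI), attention (shorter SD)
and distraction (a 1 s noise burst inside the ITI):

=====  ======  ============ ==============================================
stage  SD (s)  ITI (s)      advancement criteria (two consecutive days)
=====  ======  ============ ==============================================
S1     20      2            >=30 correct and >=40 %correct
S2     8       2            >=40 correct and >=50 %correct
S3     8       5            >=80 %accuracy and <=50 %omissions
S4     4       5            >=80 %accuracy and <=50 %omissions
S5     2       5            >=80 %accuracy and <=50 %omissions (baseline)
C1     2       9            impulsivity challenge
C2     1       5            attention challenge
C3     0.8     5            attention challenge
C4     2       5            distraction: 1 s noise within 0.5-4.5 s of ITI
C5     2       7,9,11,13    variable ITI, pseudo-random equal distribution
=====  ======  ============ ==============================================

Performance metrics over a session's trials:
``%premature = 100 * premature / trials``,
``accuracy = 100 * correct / (correct + incorrect)``,
``%omissions = 100 * omissions / trials``,
``%correct = 100 * correct / trials``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from ..clock import quantise_ms
from ..engine import TaskDefinition
from ..virtual_io import VirtualBoard
from ._base import Fixture

HOLD_S = 2.0  # post-stimulus window in which a correct poke still rewards
TIMEOUT_S = 5.0  # house-light-off timeout after a non-rewarded outcome
SESSION_MIN = 30  # sessions stop automatically after this many minutes
REWARD_UL = 20  # reward volume per correct response, microlitres

OUTCOMES = ("correct", "incorrect", "premature", "omission")


@dataclass(frozen=True)
class StageCriteria:
    """Advancement thresholds; None means the metric is not used."""

    min_correct: Optional[int] = None
    min_pct_correct: Optional[float] = None
    min_accuracy: Optional[float] = None
    max_pct_omissions: Optional[float] = None


@dataclass(frozen=True)
class FiveChoiceStage:
    name: str
    sd: float  # stimulus duration, s
    iti: Tuple[float, ...]  # ITI options, s (one entry = fixed ITI)
    criteria: Optional[StageCriteria] = None
    distraction: bool = False  # 1 s noise burst within 0.5-4.5 s of the ITI


_ATTENTION = StageCriteria(min_accuracy=80, max_pct_omissions=50)

STAGES: Dict[str, FiveChoiceStage] = {
    "S1": FiveChoiceStage("S1", 20, (2,), StageCriteria(min_correct=30, min_pct_correct=40)),
    "S2": FiveChoiceStage("S2", 8, (2,), StageCriteria(min_correct=40, min_pct_correct=50)),
    "S3": FiveChoiceStage("S3", 8, (5,), _ATTENTION),
    "S4": FiveChoiceStage("S4", 4, (5,), _ATTENTION),
    "S5": FiveChoiceStage("S5", 2, (5,), _ATTENTION),
    "C1": FiveChoiceStage("C1", 2, (9,)),
    "C2": FiveChoiceStage("C2", 1, (5,)),
    "C3": FiveChoiceStage("C3", 0.8, (5,)),
    "C4": FiveChoiceStage("C4", 2, (5,), distraction=True),
    "C5": FiveChoiceStage("C5", 2, (7, 9, 11, 13)),
}

TRAINING_ORDER = ("S1", "S2", "S3", "S4", "S5")


def _get_stage(stage: Union[str, FiveChoiceStage]) -> FiveChoiceStage:
    if isinstance(stage, FiveChoiceStage):
        return stage
    try:
        return STAGES[stage]
    except KeyError:
        raise KeyError(f"unknown 5-CSRTT stage {stage!r} "
                       f"(expected one of {sorted(STAGES)})") from None


# -- the task -----------------------------------------------------------------

def _poked_port(event: str) -> Optional[int]:
    if event.startswith("poke_"):
        return int(event.split("_", 1)[1])
    return None


def _record_trial(run, outcome: str, port) -> None:
    run.v.n_trials += 1
    run.v[f"n_{outcome}"] += 1
    run.v.trial_open = False
    run.print(f"trial {run.v.n_trials} {outcome} port {port if port else '-'}")


def five_choice_task(stage: Union[str, FiveChoiceStage] = "S5") -> TaskDefinition:
    """Build the task definition for one training/challenge stage."""
    st = _get_stage(stage)

    def init(run, event):
        if event == "entry":
            run.hw.house_light.on()
            run.set_event_timer("session_timeout", run.v.session_ms)
            run.goto_state("iti")

    def iti(run, event):
        if event == "entry":
            run.hw.house_light.on()
            run.v.trial_open = True
            run.v.iti_ms = int(run.rng.choice(run.v.iti_options_ms))
            run.timed_goto_state("stimulus", run.v.iti_ms)
            if run.v.distraction:
                onset = run.rng.uniform(500, run.v.iti_ms - 1500)
                run.set_event_timer("noise_on", onset)
                run.set_event_timer("noise_off", onset + 1000)
            return
        port = _poked_port(event)
        if port is not None:
            _record_trial(run, "premature", port)
            run.goto_state("timeout")

    def stimulus(run, event):
        if event == "entry":
            run.v.stim_port = int(run.rng.integers(1, 6))
            run.hw[f"stim_{run.v.stim_port}"].on()
            run.timed_goto_state("hold", run.v.sd_ms)
            return
        if event == "exit":
            run.hw[f"stim_{run.v.stim_port}"].off()
            return
        _respond(run, event)

    def hold(run, event):
        if event == "entry":
            run.timed_goto_state("timeout", run.v.hold_ms)
            return
        if event == "exit":
            return
        _respond(run, event)

    def _respond(run, event):
        port = _poked_port(event)
        if port is None:
            return
        if port == run.v.stim_port:
            _record_trial(run, "correct", port)
            run.goto_state("reward")
        else:
            _record_trial(run, "incorrect", port)
            run.goto_state("timeout")

    def reward(run, event):
        if event == "entry":
            run.hw.receptacle_light.on()
            run.print(f"reward {run.v.reward_ul}")
        elif event == "exit":
            run.hw.receptacle_light.off()
        elif event == "receptacle_exit":
            run.goto_state("iti")  # ITI starts when the subject leaves the receptacle

    def timeout(run, event):
        if event == "entry":
            if run.v.trial_open:  # window closed without any poke
                _record_trial(run, "omission", None)
            run.hw.house_light.off()
            run.timed_goto_state("iti", run.v.timeout_ms)

    def all_states(run, event):
        if event == "session_timeout":
            run.print("session complete")
            run.stop()
            return True
        if event == "noise_on":
            run.hw.noise.on()
            return True
        if event == "noise_off":
            run.hw.noise.off()
            return True

    events = ([f"poke_{i}" for i in range(1, 6)]
              + ["receptacle_in", "receptacle_exit",
                 "session_timeout", "noise_on", "noise_off"])
    variables = {
        "sd_ms": quantise_ms(st.sd * 1000),
        "iti_options_ms": [quantise_ms(x * 1000) for x in st.iti],
        "hold_ms": quantise_ms(HOLD_S * 1000),
        "timeout_ms": quantise_ms(TIMEOUT_S * 1000),
        "session_ms": SESSION_MIN * 60_000,
        "reward_ul": REWARD_UL,
        "distraction": st.distraction,
        "n_trials": 0, "n_correct": 0, "n_incorrect": 0,
        "n_premature": 0, "n_omission": 0,
        "stim_port": 0, "iti_ms": 0, "trial_open": False,
    }
    return TaskDefinition(
        name=f"five_choice_{st.name}",
        states=("init", "iti", "stimulus", "hold", "reward", "timeout"),
        events=tuple(events),
        initial_state="init",
        behaviour={"init": init, "iti": iti, "stimulus": stimulus, "hold": hold,
                   "reward": reward, "timeout": timeout},
        all_states=all_states,
        variables=variables,
    )


def wire_five_choice_board(board: VirtualBoard) -> None:
    """Declare the operant-box channels the task expects."""
    for i in range(1, 6):
        board.digital_input(f"poke_{i}", rising_event=f"poke_{i}", debounce=5)
        board.digital_output(f"stim_{i}")
    board.digital_input("receptacle", rising_event="receptacle_in",
                        falling_event="receptacle_exit", debounce=5)
    board.digital_output("receptacle_light")
    board.digital_output("house_light")
    board.digital_output("noise")


# -- outcome classification and metrics ---------------------------------------

@dataclass(frozen=True)
class TrialOutcome:
    outcome: str  # correct | incorrect | premature | omission
    latency: Optional[float]  # poke time minus stimulus onset, s (None if no poke)
    port: Optional[int]


def classify_outcome(pokes: Sequence[Tuple[float, int]],
                     stage: Union[str, FiveChoiceStage],
                     stim_port: int, iti_s: float,
                     hold_s: float = HOLD_S) -> TrialOutcome:
    """Deterministic trial classification from the poke/timing record.

    ``pokes`` are (time_s_from_trial_start, port) pairs; the trial starts at
    ITI onset and the stimulus comes on after ``iti_s``.  Times are quantised
    to the engine's 1 ms grid, and ties at window boundaries resolve the way
    the running machine does (an input at the same tick as an elapsing window
    timer is processed first), so a poke exactly at the ITI end is premature
    and a correct-port poke exactly at SD + hold is still correct.
    """
    st = _get_stage(stage)
    iti_ms = quantise_ms(iti_s * 1000)
    window_end = iti_ms + quantise_ms(st.sd * 1000) + quantise_ms(hold_s * 1000)
    for t_s, port in sorted(pokes):
        tick = quantise_ms(t_s * 1000)
        if tick > window_end:
            break  # poke after the window: trial already an omission
        latency = (tick - iti_ms) / 1000.0
        if tick <= iti_ms:
            return TrialOutcome("premature", latency, port)
        if port == stim_port:
            return TrialOutcome("correct", latency, port)
        return TrialOutcome("incorrect", latency, port)
    return TrialOutcome("omission", None, None)


def session_metrics(outcomes) -> Dict[str, Optional[float]]:
    """Performance metrics from a session's trial outcomes.

    ``outcomes`` is an iterable of outcome strings or a mapping of counts.
    Zero-denominator metrics are returned as None rather than a number.
    """
    if isinstance(outcomes, Mapping):
        counts = {k: int(outcomes.get(k, 0)) for k in OUTCOMES}
    else:
        counts = {k: 0 for k in OUTCOMES}
        for o in outcomes:
            if o not in counts:
                raise ValueError(f"unknown trial outcome {o!r}")
            counts[o] += 1
    n_trials = sum(counts.values())
    responded = counts["correct"] + counts["incorrect"]

    def pct(num, den):
        return 100.0 * num / den if den else None

    return {
        "n_trials": n_trials,
        "n_correct": counts["correct"],
        "n_incorrect": counts["incorrect"],
        "n_premature": counts["premature"],
        "n_omission": counts["omission"],
        "pct_correct": pct(counts["correct"], n_trials),
        "accuracy": pct(counts["correct"], responded),
        "pct_omissions": pct(counts["omission"], n_trials),
        "pct_premature": pct(counts["premature"], n_trials),
    }


def metrics_from_session(session) -> Dict[str, Optional[float]]:
    """Session metrics recomputed from the per-trial print lines of a data file."""
    outcomes = []
    for _, text in session.prints:
        parts = text.split()
        if len(parts) >= 3 and parts[0] == "trial":
            outcomes.append(parts[2])
    return session_metrics(outcomes)


def criteria_met(stage: Union[str, FiveChoiceStage], metrics: Mapping) -> bool:
    """Whether one day's metrics satisfy the stage's advancement criteria."""
    st = _get_stage(stage)
    if st.criteria is None:
        return False
    c = st.criteria
    checks = []
    if c.min_correct is not None:
        checks.append(metrics.get("n_correct") is not None
                      and metrics["n_correct"] >= c.min_correct)
    if c.min_pct_correct is not None:
        checks.append(metrics.get("pct_correct") is not None
                      and metrics["pct_correct"] >= c.min_pct_correct)
    if c.min_accuracy is not None:
        checks.append(metrics.get("accuracy") is not None
                      and metrics["accuracy"] >= c.min_accuracy)
    if c.max_pct_omissions is not None:
        checks.append(metrics.get("pct_omissions") is not None
                      and metrics["pct_omissions"] <= c.max_pct_omissions)
    return bool(checks) and all(checks)


def stage_controller(current_stage: str, daily_metrics: Sequence[Mapping]) -> str:
    """Next training stage given the day-by-day metric history on the current
    stage.  Advances exactly one stage when the criteria are met on the two
    most recent consecutive days; never skips; S5 is terminal (baseline);
    challenge stages never advance."""
    st = _get_stage(current_stage)
    if st.name not in TRAINING_ORDER or st.name == TRAINING_ORDER[-1]:
        return st.name
    if len(daily_metrics) < 2:
        return st.name
    if criteria_met(st, daily_metrics[-1]) and criteria_met(st, daily_metrics[-2]):
        return TRAINING_ORDER[TRAINING_ORDER.index(st.name) + 1]
    return st.name


# -- synthetic agent -----------------------------------------------------------

@dataclass(frozen=True)
class AgentSpec:
    """Stochastic stand-in for the animal: per-trial outcome-class
    probabilities and response latency ranges."""

    p_correct: float = 0.6
    p_incorrect: float = 0.1
    p_premature: float = 0.2
    p_omit: float = 0.1
    min_latency_s: float = 0.2  # earliest poke after stimulus onset
    consume_s: float = 1.5  # time spent in the receptacle after a reward

    def __post_init__(self):
        probs = (self.p_correct, self.p_incorrect, self.p_premature, self.p_omit)
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"outcome probabilities must be in [0,1] and sum to 1, got {probs}")


class FiveChoiceAgent:
    """Closed-loop agent injecting poke edges as the session unfolds.

    On each ITI entry it draws the trial's planned outcome class; premature
    plans poke during the ITI, correct/incorrect plans poke the lit (or a
    different) port at a random latency inside the response window, omission
    plans do nothing.  After a reward it enters and exits the receptacle,
    which starts the next ITI.
    """

    def __init__(self, spec: AgentSpec, board: VirtualBoard, seed=0):
        self.spec = spec
        self.board = board
        self.rng = np.random.default_rng(seed)
        self.engine = None
        self._plan = None
        self.planned: List[str] = []  # planned class per trial, for cross-checks

    def attach(self, engine) -> None:
        self.engine = engine
        engine.add_state_listener(self.on_state)

    def _poke(self, t: float, port: int) -> None:
        self.board[f"poke_{port}"].inject(t, "rising")

    def on_state(self, state: str, t: int) -> None:
        run, spec, rng = self.engine, self.spec, self.rng
        if state == "iti":
            self._plan = rng.choice(
                ["correct", "incorrect", "premature", "omission"],
                p=[spec.p_correct, spec.p_incorrect, spec.p_premature, spec.p_omit])
            self.planned.append(str(self._plan))
            if self._plan == "premature":
                self._poke(t + rng.uniform(0.25, 0.9) * run.v.iti_ms,
                           int(rng.integers(1, 6)))
        elif state == "stimulus":
            window_ms = run.v.sd_ms + run.v.hold_ms
            latency = rng.uniform(spec.min_latency_s * 1000,
                                  max(spec.min_latency_s * 1000 + 1, window_ms - 100))
            if self._plan == "correct":
                self._poke(t + latency, run.v.stim_port)
            elif self._plan == "incorrect":
                others = [p for p in range(1, 6) if p != run.v.stim_port]
                self._poke(t + latency, int(rng.choice(others)))
        elif state == "reward":
            recep = self.board["receptacle"]
            recep.inject(t + 200, "rising")
            recep.inject(t + 200 + spec.consume_s * 1000, "falling")


class ScriptedPoker:
    """Deterministic single-poke driver for boundary probing: pokes once per
    trial, at a fixed offset from entry into ``poke_state``."""

    def __init__(self, board: VirtualBoard, poke_state: str, offset_ms: float,
                 correct_port: bool = True, exit_receptacle_after_ms: float = 1500):
        self.board = board
        self.poke_state = poke_state
        self.offset_ms = offset_ms
        self.correct_port = correct_port
        self.exit_after = exit_receptacle_after_ms
        self.engine = None

    def attach(self, engine) -> None:
        self.engine = engine
        engine.add_state_listener(self.on_state)

    def on_state(self, state: str, t: int) -> None:
        run = self.engine
        if state == self.poke_state:
            if self.poke_state in ("stimulus", "hold"):
                port = run.v.stim_port if self.correct_port else (run.v.stim_port % 5) + 1
            else:
                port = 1
            self.board[f"poke_{port}"].inject(t + self.offset_ms, "rising")
        elif state == "reward":
            recep = self.board["receptacle"]
            recep.inject(t + 200, "rising")
            recep.inject(t + self.exit_after, "falling")


def probe_trial(stage: Union[str, FiveChoiceStage] = "S5", *,
                poke_state: str = "stimulus", offset_ms: float = 500,
                correct_port: bool = True, seed: int = 0):
    """Run a fresh session long enough for one trial with a single scripted
    poke; return ``(outcome_str_or_None, engine)``."""
    from ..clock import Scheduler
    from ..engine import Engine

    st = _get_stage(stage)
    sched = Scheduler()
    board = VirtualBoard(sched)
    wire_five_choice_board(board)
    defn = five_choice_task(st)
    engine = Engine(defn, sched, board=board, seed=seed)
    poker = ScriptedPoker(board, poke_state, offset_ms, correct_port)
    poker.attach(engine)
    horizon = (max(st.iti) + st.sd + HOLD_S + TIMEOUT_S) * 1000 + 3000
    engine.start_run()
    sched.advance_to(horizon)
    outcome = None
    for name in OUTCOMES:
        if engine.v[f"n_{name}"] >= 1:
            outcome = name
            break
    return outcome, engine


# -- fixture -------------------------------------------------------------------

class FiveChoiceFixture(Fixture):
    name = "five-choice"
    description = "5-CSRTT stage session driven by a stochastic agent"
    default_params = {
        "stage": "S5",
        "p_correct": 0.6, "p_incorrect": 0.1, "p_premature": 0.2, "p_omit": 0.1,
    }
    default_duration_ms = (SESSION_MIN + 2) * 60_000  # session self-stops at 30 min

    def build(self, board: VirtualBoard, params: dict) -> TaskDefinition:
        wire_five_choice_board(board)
        return five_choice_task(params["stage"])

    def drive(self, engine, params: dict, seed: int) -> None:
        spec = AgentSpec(p_correct=params["p_correct"],
                         p_incorrect=params["p_incorrect"],
                         p_premature=params["p_premature"],
                         p_omit=params["p_omit"])
        agent = FiveChoiceAgent(spec, engine.board, seed=[seed, 1])
        agent.attach(engine)
        engine.scratch["agent"] = agent
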