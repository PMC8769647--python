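"""5-CSRTT fixture: outcome windows, timeouts, metrics, stage transitions,
variable ITI, and agent-driven sessions."""

import itertools

import numpy as np
import pytest

from behavsim import parse_session, state_intervals
from behavsim.tasks import run_fixture
from behavsim.tasks.five_choice import (HOLD_S, STAGES, TIMEOUT_S, AgentSpec,
                                        classify_outcome, criteria_met,
                                        five_choice_task, metrics_from_session,
                                        probe_trial, session_metrics,
                                        stage_controller)


def test_stage_table_matches_the_training_protocol():
    assert (STAGES["S1"].sd, STAGES["S1"].iti) == (20, (2,))
    assert (STAGES["S5"].sd, STAGES["S5"].iti) == (2, (5,))
    assert STAGES["C1"].iti == (9,)
    assert STAGES["C5"].iti == (7, 9, 11, 13)
    assert STAGES["C3"].sd == 0.8
    assert STAGES["C4"].distraction


# -- single-trial semantics ----------------------------------------------------

def test_correct_poke_during_stimulus_is_rewarded():
    outcome, eng = probe_trial("S5", poke_state="stimulus", offset_ms=500)
    assert outcome == "correct"
    assert any(p.payload.startswith("reward 20") for p in eng.log
               if p.kind == "print")


def test_wrong_port_poke_during_stimulus_is_incorrect():
    outcome, _ = probe_trial("S5", poke_state="stimulus", offset_ms=500,
                             correct_port=False)
    assert outcome == "incorrect"


def test_poke_during_iti_is_premature():
    outcome, _ = probe_trial("S5", poke_state="iti", offset_ms=1000)
    assert outcome == "premature"


def test_no_poke_at_all_is_an_omission():
    outcome, _ = probe_trial("S5", poke_state="reward", offset_ms=0)
    assert outcome == "omission"


def test_hold_window_boundary_at_two_seconds_after_stimulus_offset():
    """Grid search at 0.1 s resolution: a correct-port poke up to and
    including 2.0 s after stimulus offset is correct; beyond it, the trial is
    an omission."""
    sd_ms = 2000  # stage S5
    for k in range(31):  # latencies 0.0 .. 3.0 s after stimulus offset
        latency_ms = 100 * k
        outcome, _ = probe_trial("S5", poke_state="stimulus",
                                 offset_ms=sd_ms + latency_ms)
        expected = "correct" if latency_ms <= 2000 else "omission"
        assert outcome == expected, f"latency {latency_ms} ms -> {outcome}"


def test_sd_boundary_poke_still_lands_in_the_stimulus_window():
    # exactly at SD the input outranks the stimulus->hold timer
    outcome, _ = probe_trial("S5", poke_state="stimulus", offset_ms=2000)
    assert outcome == "correct"


def test_nonrewarded_outcomes_turn_house_light_off_for_five_seconds():
    for kwargs in (dict(poke_state="stimulus", offset_ms=500, correct_port=False),
                   dict(poke_state="iti", offset_ms=1000)):
        _, eng = probe_trial("S5", **kwargs)
        house = eng.board["house_light"].history
        offs = [t for t, lvl in house if lvl == 0]
        ons = [t for t, lvl in house if lvl == 1]
        dark = [on - off for off, on in zip(offs, ons[1:])]
        assert len(dark) >= 1
        assert set(dark) == {int(TIMEOUT_S * 1000)}


def test_stimulus_light_is_lit_on_the_cued_port_for_sd():
    outcome, eng = probe_trial("S5", poke_state="reward", offset_ms=0)  # omission
    port = eng.v.stim_port
    pulses = eng.board[f"stim_{port}"].pulses()
    assert len(pulses) == 1
    t_on, t_off = pulses[0]
    assert t_off - t_on == eng.v.sd_ms


def test_session_autostops_at_thirty_minutes(tmp_path):
    path = tmp_path / "s.txt"
    p = run_fixture("five-choice", seed=1, session_path=path)
    assert p.engine.summary()["phase"] == "stopped"
    session = parse_session(path)
    assert session.end_time == 30 * 60_000


# -- classification oracle vs the running machine ------------------------------

def test_classifier_agrees_with_the_simulated_machine_on_probe_grid():
    sd_ms = 2000
    for offset_ms, correct_port in itertools.product(
            [100, 1000, 1999, 2000, 2001, 3000, 3999, 4000, 4001, 4500],
            [True, False]):
        outcome, eng = probe_trial("S5", poke_state="stimulus",
                                   offset_ms=offset_ms, correct_port=correct_port)
        iti_s = eng.v.iti_ms / 1000.0
        port = eng.v.stim_port if correct_port else (eng.v.stim_port % 5) + 1
        predicted = classify_outcome(
            [(iti_s + offset_ms / 1000.0, port)], "S5",
            stim_port=eng.v.stim_port, iti_s=iti_s)
        assert outcome == predicted.outcome, (offset_ms, correct_port)


def test_classifier_iti_boundary_assigns_boundary_poke_to_premature():
    r = classify_outcome([(5.0, 3)], "S5", stim_port=3, iti_s=5.0)
    assert r.outcome == "premature"
    r = classify_outcome([(5.001, 3)], "S5", stim_port=3, iti_s=5.0)
    assert r.outcome == "correct"


def test_classifier_ignores_pokes_after_the_window():
    r = classify_outcome([(20.0, 3)], "S5", stim_port=3, iti_s=5.0)
    assert r.outcome == "omission" and r.port is None


# -- metrics -------------------------------------------------------------------

def test_metric_formulas_match_hand_arithmetic():
    outcomes = (["correct"] * 8 + ["incorrect"] * 2 + ["premature"] * 5
                + ["omission"] * 5)
    m = session_metrics(outcomes)
    assert m["n_trials"] == 20
    assert m["accuracy"] == pytest.approx(80.0)  # 100 * 8 / (8 + 2)
    assert m["pct_omissions"] == pytest.approx(25.0)  # 100 * 5 / 20
    assert m["pct_premature"] == pytest.approx(25.0)
    assert m["pct_correct"] == pytest.approx(40.0)


def test_all_correct_gives_accuracy_100_and_other_rates_zero():
    m = session_metrics(["correct"] * 12)
    assert m["accuracy"] == 100.0
    assert m["pct_omissions"] == 0.0 and m["pct_premature"] == 0.0


def test_zero_denominators_yield_undefined_markers_not_numbers():
    empty = session_metrics([])
    assert empty["accuracy"] is None and empty["pct_omissions"] is None
    no_response = session_metrics(["omission"] * 4)
    assert no_response["accuracy"] is None
    assert no_response["pct_omissions"] == 100.0


def test_metrics_accept_count_mappings_and_reject_unknown_outcomes():
    assert session_metrics({"correct": 3, "incorrect": 1})["accuracy"] == 75.0
    with pytest.raises(ValueError, match="unknown trial outcome"):
        session_metrics(["banana"])


# -- stage controller ----------------------------------------------------------

def day(n_correct=0, pct_correct=0.0, accuracy=0.0, pct_omissions=100.0):
    return {"n_correct": n_correct, "pct_correct": pct_correct,
            "accuracy": accuracy, "pct_omissions": pct_omissions}


def test_two_qualifying_days_advance_one_stage():
    history = [day(31, 41), day(35, 45)]
    assert stage_controller("S1", history) == "S2"


def test_single_qualifying_day_does_not_advance():
    assert stage_controller("S1", [day(31, 41)]) == "S1"
    assert stage_controller("S1", [day(31, 41), day(10, 5)]) == "S1"
    assert stage_controller("S1", [day(10, 5), day(31, 41)]) == "S1"


def test_terminal_and_challenge_stages_never_advance():
    good = [day(99, 99, 99, 0)] * 2
    assert stage_controller("S5", good) == "S5"
    assert stage_controller("C1", good) == "C1"


def test_stage_controller_matches_brute_force_over_all_small_histories():
    """Exhaustive enumeration: every 2-day window of qualifying/failing days,
    for every training stage, against an independent rule check."""
    qualifying = {
        "S1": day(30, 40), "S2": day(40, 50),
        "S3": day(accuracy=80, pct_omissions=50),
        "S4": day(accuracy=80, pct_omissions=50),
    }
    failing = {
        "S1": day(29, 40), "S2": day(40, 49.9),
        "S3": day(accuracy=79.9, pct_omissions=50),
        "S4": day(accuracy=80, pct_omissions=50.1),
    }
    order = ["S1", "S2", "S3", "S4", "S5"]
    for stage in qualifying:
        for bits in itertools.product([0, 1], repeat=4):
            history = [qualifying[stage] if b else failing[stage] for b in bits]
            expected = (order[order.index(stage) + 1]
                        if bits[-1] == 1 and bits[-2] == 1 else stage)
            assert stage_controller(stage, history) == expected, (stage, bits)


def test_thresholds_are_inclusive_per_the_protocol_table():
    assert criteria_met("S1", day(30, 40))
    assert not criteria_met("S1", day(29, 40))
    assert criteria_met("S3", day(accuracy=80, pct_omissions=50))
    assert not criteria_met("S3", day(accuracy=80, pct_omissions=50.01))
    assert not criteria_met("S3", {"accuracy": None, "pct_omissions": 0})


# -- variable ITI (C5) ---------------------------------------------------------

def test_variable_iti_samples_all_four_durations_about_equally(tmp_path):
    """C5 draws ITIs from {7,9,11,13} s pseudo-randomly with equal
    probability; observed ITI-state durations over a long run are
    near-uniform."""
    path = tmp_path / "s.txt"
    run_fixture("five-choice", seed=2, session_path=path,
                params={"stage": "C5", "p_correct": 0.0, "p_incorrect": 0.0,
                        "p_premature": 0.0, "p_omit": 1.0,
                        "duration_ms": 125 * 60_000},
                variables={"session_ms": 120 * 60_000},
                )
    session = parse_session(path)
    durations = [b - a for a, b in state_intervals(session, "iti")[:-1]]
    counts = {d: durations.count(d) for d in (7000, 9000, 11000, 13000)}
    n = len(durations)
    assert n > 300 and sum(counts.values()) == n
    for d, c in counts.items():
        assert 0.17 < c / n < 0.33, counts


# -- agent-driven sessions -----------------------------------------------------

def test_perfect_agent_scores_accuracy_100(tmp_path):
    path = tmp_path / "s.txt"
    run_fixture("five-choice", seed=3, session_path=path,
                params={"p_correct": 1.0, "p_incorrect": 0.0,
                        "p_premature": 0.0, "p_omit": 0.0},
                variables={"session_ms": 10 * 60_000})
    m = metrics_from_session(parse_session(path))
    assert m["n_trials"] > 20
    assert m["accuracy"] == 100.0
    assert m["pct_premature"] == 0.0 and m["pct_omissions"] == 0.0


def test_fully_omitting_agent_yields_only_omissions():
    p = run_fixture("five-choice", seed=3,
                    params={"p_correct": 0.0, "p_incorrect": 0.0,
                            "p_premature": 0.0, "p_omit": 1.0},
                    variables={"session_ms": 5 * 60_000})
    eng = p.engine
    assert eng.v.n_trials == eng.v.n_omission > 10


def test_logged_outcomes_match_the_agent_planned_draws(tmp_path):
    path = tmp_path / "s.txt"
    p = run_fixture("five-choice", seed=6, session_path=path,
                    variables={"session_ms": 10 * 60_000})
    agent = p.engine.scratch["agent"]
    m = metrics_from_session(parse_session(path))
    realised = [text.split()[2] for _, text in parse_session(path).prints
                if text.startswith("trial")]
    # the agent plans one class per started trial; every completed trial
    # realises its plan (map omission plans onto recorded omissions)
    assert realised == agent.planned[:len(realised)]
    assert m["n_trials"] == len(realised)


def test_outcome_partition_counts_sum_to_trial_count():
    p = run_fixture("five-choice", seed=8,
                    variables={"session_ms": 10 * 60_000})
    eng = p.engine
    total = (eng.v.n_correct + eng.v.n_incorrect + eng.v.n_premature
             + eng.v.n_omission)
    assert total == eng.v.n_trials > 20


def test_agent_spec_validates_probability_simplex():
    with pytest.raises(ValueError, match="sum to 1"):
        AgentSpec(p_correct=0.9, p_incorrect=0.9, p_premature=0.0, p_omit=0.0)


def test_session_files_are_deterministic_under_seed(tmp_path):
    p1 = tmp_path / "a.txt"
    p2 = tmp_path / "b.txt"
    run_fixture("five-choice", seed=11, session_path=p1,
                variables={"session_ms": 5 * 60_000})
    run_fixture("five-choice", seed=11, session_path=p2,
                variables={"session_ms": 5 * 60_000})
    assert p1.read_bytes() == p2.read_bytes()


def test_distraction_stage_plays_noise_inside_the_iti():
    p = run_fixture("five-choice", seed=4, params={"stage": "C4"},
                    variables={"session_ms": 5 * 60_000})
    noise = p.engine.board["noise"].pulses()
    assert len(noise) > 5
    assert all(b - a == 1000 for a, b in noise)
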