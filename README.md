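# behavsim

A desk-runnable, discrete-event simulator for behavioural neuroscience
experiment control.  It lets you develop, test and reason about operant /
head-fixed task logic — the kind normally executed by a microcontroller wired
to nose-pokes, LEDs and lickometers — entirely on a laptop, with a
deterministic simulated millisecond clock and virtual hardware channels in
place of the physical box and oscilloscope.

It is written for behavioural researchers and tool builders who want to:

* prototype and regression-test task definitions (trial structure, timers,
  outcome classification) before an animal ever sees them;
* generate realistic synthetic session data files for analysis pipelines;
* verify timing semantics (event priorities, 1 ms tick quantisation) that are
  hard to probe on hardware;
* align timestamps across acquisition systems using random-interval
  sync-pulse trains.

## The model

Tasks are **extended state machines**: a set of named states and events, one
*state behaviour function* per state, plus task variables and arbitrary code.
Whenever an event occurs, the current state's behaviour function is called
with the event name; reserved pseudo-events `entry` / `exit` fire on state
transitions, and an optional `all_states` hook sees every external event
first (and may suppress it), allowing logic that runs in parallel with the
main state set.  Timers can trigger events or state transitions
(`timed_goto_state`) after a delay, and can be cancelled, paused and
un-paused.

The engine runs on a simulated clock with 1 ms resolution.  Within a tick,
due items are delivered in a fixed priority order — **input edges, then
elapsing timers (in arming order), then task-raised events** — mirroring an
update loop that services hardware interrupts ahead of timers ahead of
communication.  Continuous-time stimulus edges are quantised *up* to the next
tick, so every reaction is late by strictly less than 1 ms, the simulated
counterpart of timing errors being uniformly spread across one clock tick on
real hardware.  Identical task + stimulus script + seed gives byte-identical
session files.

The library ships fixture tasks exercising every engine feature: the
three-presses-light-the-LED worked example, timing-validation tasks
(input follower, 10 ms triggered pulses, 200 Hz Poisson event load), a full
**5-choice serial reaction time task** (staged training S1–S5, challenge
protocols C1–C5, outcome classification, performance metrics
`accuracy = 100·correct/(correct+incorrect)`,
`%omissions = 100·omissions/trials`, `%premature = 100·premature/trials`,
and the two-consecutive-day stage-advancement rule), and a Go/NoGo lick task
— driven by scripted stimuli or stochastic closed-loop agents standing in
for the animal.

## Worked example

The introductory task: pressing a button three times turns an LED on for 1 s.
Run it for 10 s of simulated time with button presses scripted at 1 Hz:

```python
from behavsim.tasks import run_fixture
from behavsim.data_import import parse_session, state_intervals

p = run_fixture("button-led", seed=1, params={"duration_ms": 10_000},
                session_path="demo.txt")
print("LED pulses:", p.board["LED"].pulses())

s = parse_session("demo.txt")
print("press count:", s.times["press"].size)
print("LED_on intervals:", state_intervals(s, "LED_on"))
```

prints

```
LED pulses: [(2000, 3000), (6000, 7000)]
press count: 10
LED_on intervals: [(2000, 3000), (6000, 7000)]
```

The third press lands at t = 2000 ms and the LED is on for exactly
1000 ms of simulated time.  The press at t = 3000 ms arrives at the same
tick as the timer returning the machine to `wait_for_press`, and inputs
outrank timers, so it is delivered while the LED is still on and is ignored
— which is why the second LED pulse needs presses 4–6 and starts at 6000 ms.
The state intervals reconstructed from the written data file agree exactly
with the virtual LED channel's history.

The same session is available from a shell:

```bash
behavsim run-task button-led --duration 10000 --seed 1 --out demo.txt
behavsim parse demo.txt
behavsim list-fixtures
```

## Session data files

Sessions are line-oriented UTF-8 text:

```
I <key> <value>      header: experiment, task, task_hash, subject, start_time, seed
S {"state": id, …}   state name → ID map      (states and events share one ID space)
E {"event": id, …}   event name → ID map
V <t> <name> <json>  variable changed away from its task-file default
D <t> <id>           event occurrence / state entry, t in ms from run start
P <t> <text>         user print line
! <t> <json-string>  error traceback
Z <t>                end of session
```

Timestamps are non-decreasing integers in ms.  Variables changed before the
run yield `V` lines at t = 0 ahead of any `D` line, and the task source is
archived next to the data as `<task>_<crc32>.py` with the same hash recorded
in the header, so every file documents exactly which task version and
parameters produced it.  Analog channels go to companion binary `.pca` files
of little-endian `(int32 ms, int32 value)` pairs.
`behavsim.data_import.parse_session` returns both a name → times-array dict
and the ordered record list.

Multi-subject experiments are described by YAML configs (subjects, shared and
per-subject variable overrides, `persistent` variables restored on the next
run, `summary` variables collected into a per-subject TSV table) and run
headlessly with `behavsim run-experiment`.  Clock alignment between systems:
`behavsim sync-align A.csv B.csv --tol 2` matches two recordings of a
random-interval pulse train and fits `t_B = a·t_A + b`.

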