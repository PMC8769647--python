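# Methods

## Execution model

The simulator executes extended-state-machine tasks on an integer
millisecond clock starting at 0.  Three classes of pending items exist —
scheduled **input** edges/threshold crossings, armed **timers**, and
task-raised **api** events — and within one tick they are delivered in that
order, FIFO within a class and in arming order among timers.  Each delivered
item is dispatched to the task engine before the next is taken, so a handler
that arms a zero-delay timer sees it fire within the same tick, immediately
after the current dispatch.  The input-before-timer rule is the contract for
all boundary ties: a poke arriving at the same tick as a closing response
window is processed inside the window.

The scheduler does not literally iterate every tick; it jumps the clock to
the next due item's time.  Delivered timestamps and ordering are provably
identical to a tick-by-tick loop (nothing can become due in the skipped
interval: runtime insertions require `t >= now`), and a 30-minute 5-CSRTT
session simulates in tens of milliseconds.  The simulation models the update
loop's *priority ordering* only, not per-event processing cost; queue
overflow under sustained event rates is a hardware property and out of
scope.

Real-valued stimulus times are quantised up, `tick = ceil(t)` (with a 1e-9
guard against float fuzz), so the simulated reaction to any continuous-time
edge is late by strictly less than 1 ms.  With a drive whose edges drift
against the millisecond grid (e.g. a 51 Hz square wave), reaction lags
sample the whole [0, 1) ms interval — the simulated counterpart of pulse
timing errors being approximately uniform across one clock tick on real
hardware.  Hardware latency and jitter distributions themselves are
explicitly not reproduced.

## Engine semantics where the design was open

* `all_states` is consulted *before* the state behaviour and suppresses it
  by returning True.  This interception-capable ordering is the more
  expressive contract (a pass-through hook cannot emulate suppression, but a
  suppressing hook can emulate pass-through by returning nothing).
  `entry`/`exit` are reserved, delivered only to the state behaviour, and
  cannot be raised as events.
* Any state transition disarms pending `timed_goto_state` timers, keeping
  behaviour consistent with a state-diagram reading: a timed transition
  belongs to the state that armed it.
* `goto_state` from within an exit handler errors the run (unbounded
  recursion guard); exceptions inside behaviour functions are caught, logged
  as a traceback record, and terminate the run in an `errored` phase without
  taking down sibling subjects in an experiment.
* Ties among timers at one tick break by arming order, and unpausing
  restores `expiry = now + remaining`, so total paused time adds exactly to
  the effective delay.
* External `set_variable` calls log a variable-change record iff the value
  differs from the task-file default; writes from inside behaviour code
  (per-trial counters) are not logged.  This keeps data files
  self-documenting about parameter deviations without flooding them.
* Each run draws randomness from a `numpy` generator seeded from the run
  seed recorded in the session header; closed-loop agents use an
  independently derived stream so task and agent draws cannot interleave.

## Virtual hardware

Digital inputs map accepted edges one-to-one onto framework events (rising
and/or falling).  Debounce is a refractory filter: after an accepted edge,
edges within the configured window are discarded entirely.  The engine
default is 0 ms; fixtures modelling mechanical pokes use 5 ms.  Analog
inputs sample a waveform function at a fixed rate (validation conditions use
1 kHz) and emit threshold events on strict crossings with state memory: an
upper event fires at the first sample strictly above threshold after the
signal was at-or-below it, and re-arms only when the signal returns — a
signal sitting beyond threshold does not re-trigger.  Outputs record level
*changes* with timestamps; idempotent sets are recorded once, and analyses
read pulse durations from this history as one would from a scope trace.

Stimulus generators: square waves place rising edges at k/f seconds and
falling at (k+0.5)/f; Poisson trains draw i.i.d. exponential gaps.  Both are
seeded and reproducible.  A declarative script format (YAML: per channel,
one of `edges`, `square_wave`, `poisson`, `sine`) binds scripted worlds to
boards without code.

## Session files and import

The line dialect (`I/S/E/D/P/V/!/Z`, documented in the README) is fixed by
this package; byte compatibility with any particular hardware ecosystem's
files is not claimed.  States and events share one integer ID space so `D`
lines are unambiguous.  The task-source digest is CRC-32 rendered as 8 hex
characters — short, ubiquitous and content-identifying; it guards against
version mix-ups, not adversaries.  Analog data uses interleaved int32
(timestamp, value) pairs: fixed-width, self-delimiting, trivially readable
from any language.  The importer rebuilds two representations (name →
sorted times array; ordered record list), validates header completeness,
ID membership and timestamp monotonicity with line numbers in every
diagnostic, and reconstructs state occupancy intervals from consecutive
entries, closing the final interval at the session end time (the dialect
logs entries only).

## Sync alignment

Pulse trains use uniform random intervals, 500–1500 ms by default:
sub-second granularity with high interval entropy, giving effectively
unique interval fingerprints at typical session lengths.  Matching slides
one interval sequence along the other and counts agreements within `tol`
(default 2 ms); the best lag must beat the runner-up by ≥ 3 agreeing
intervals, otherwise a `MatchError` is raised rather than a guess returned.
Before comparison the median interval ratio is snapped to the nearest power
of ten, handling unit mismatches (s vs ms) while leaving physiological
drift (|a−1| ~ 1e-4) to the tolerance.  The fitted conversion is an affine
least-squares map; a piecewise-linear variant interpolating through matched
pulses is available for non-constant drift.  Conversions outside the
matched range are flagged as extrapolation.  Under the tested conditions —
drift 1 ± 1e-4, offsets up to ±2 min, jitter ≤ tol/2, up to half the
leading pulses missing — slope is recovered within 1e-5 and offset within
5 ms across 100 seeds.

## The 5-CSRTT fixture

Trial loop: ITI → stimulus in one pseudorandomly chosen port (seeded
uniform over the 5 ports, immediate repeats allowed) for the stage's SD →
2 s hold window → outcome.  A poke in the lit port during SD or hold is
correct (receptacle light + 20 µl reward record); any poke during the ITI
is premature; a wrong-port poke during SD/hold is incorrect; no poke is an
omission.  Non-rewarded outcomes trigger a 5 s timeout with the house light
off, and the next ITI starts at timeout end or when the subject exits the
receptacle after collecting a reward.  Sessions auto-stop at 30 min.  Stage
parameters and advancement criteria (two consecutive qualifying days, never
skipping a stage) follow the staged-training table in the module docstring;
the boundary tie between the last instant of the ITI and the first instant
of the stimulus is assigned to the ITI (premature), which is exactly what
the input-before-timer rule produces in the running machine.  The pure
`classify_outcome` function reimplements this mapping from a trial's poke
record alone and is cross-checked against the engine in the tests.

`%correct` is computed as 100·correct/trials (the companion of `#correct`
in the S1/S2 criteria); `accuracy` uses responded trials
(correct+incorrect) as its denominator.  Zero-denominator metrics return
`None`, never a number.

## Synthetic agents

Agents replace the animal with per-trial draws over outcome classes
(defaults: p_correct 0.6, p_incorrect 0.1, p_premature 0.2, p_omit 0.1 — a
mid-training mixed performance profile) and uniform response latencies
inside the relevant windows, injecting poke/lick edges at runtime as the
session unfolds (poke times depend on trial timing, so the loop is closed
through a state-entry listener).  Agents emulate *contingent timing*, not
animal learning: no within-session adaptation, no latency structure beyond
the uniform draw, no partial pokes or sensor chatter beyond the configured
debounce.  Passing tests therefore certify the task logic, logging and
timing machinery — not any behavioural prediction about real mice.

## Problem sizes used in the checks

Worked example 10 s at 1 Hz presses; follower/pulse validation 50 s of
51 Hz drive (2550 pulses); Poisson load 2 × 200 Hz for 100 s (~40 000
events); 5-CSRTT sessions 30 simulated minutes (~200 trials), with 5–10 min
variants where only counts matter; hold-window grid at 0.1 s over 0–3 s;
sync recovery over 100 seeds of ~2-minute trains.  Each check runs in well
under a second of wall time; the full suite completes in a few seconds.

## Known limitations

Single-board semantics only (no serial devices, audio synthesis or rotary
physics); "parallel" experiment execution is sequential per subject, which
the per-subject scheduler/seed design makes observationally equivalent;
the event queue is unbounded (no overflow modelling); analog streaming is
offline-scripted rather than chunked in real time; and the Go/NoGo task's
window/timeout durations are package defaults (ITI 3 s, stimulus 1 s,
response window 1.5 s, timeout 2 s, drink 1 s) rather than published
values, configurable per run.
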