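# Methods

## Model

`adlcoach` treats ADL coaching as a deterministic production system over a
working memory of typed facts. A **scenario** is an ordered list of target
behaviors; a **behavior** is a `(space, sensor_type, required_state)` triple.
While a scenario is active exactly one step is *ongoing*; each sensor state
change is judged against the scenario:

- **TARGET** — it equals the ongoing step's triple: the step is marked done
  at the current clock value and the next step opens (or the scenario ends
  after the last step).
- **GENERAL** — it is declared as expected background activity (e.g. light
  switching), or it is not registered to the scenario at all: it is logged
  and nothing else happens.
- **ABNORMAL** — it matches another behavior registered to the scenario (a
  different step's target, or a declared known-wrong action such as opening
  the refrigerator mid-task): corrective coaching is delivered immediately,
  contrasting what was observed with the step's target. Declared generals
  are checked before the abnormal search, so a triple can never be both.

Timeout coaching is anchored at the previous step's completion time (the
scenario start for step 1). With per-user limit `L`, the first prompt fires
when the clock reaches `anchor + L`; while inactivity continues, an
identical prompt fires each further `L` after the previous one. The
classification of behaviors into these cases, plus the timeout rule, fully
determines when coaching occurs.

### Rule realization

Rules are condition/action units over the fact store with a deterministic
agenda — priority order *scenario end > behavior judging > timeout
coaching*, ties by declaration order — i.e. CLIPS-style match–fire
semantics without a CLIPS dependency. The fact kinds are `sensor`,
`sensor_updated` (transient), `scenario_active`, `step_state`, `adl_log`
and `clock`. Scenario end retracts every scenario-scoped fact (step states,
the active-scenario fact, the accumulated log facts) and leaves sensor
objects intact, so a restart is indistinguishable from a fresh engine.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| step time limit | 3000 | ms | a practical prompting interval for short household steps; overridable per user and per step, since performance varies strongly between users |
| power threshold on / off | 50 / 10 | W | a hysteresis pair bracketing typical appliance standby vs. active draw; a single threshold is used when only one is configured |
| power ramp rise time | 500 | ms | appliances change draw gradually; the simulator's linear ramp makes ON/OFF recognition lag the action, as real power monitoring does |
| max coaching repeats | 10 | — | bounds unattended runs; a scenario never ends by timeout, only by completion or operator abort |
| delivery latency sink | 495 | ms | a representative cloud TTS round trip, injected as configuration for latency studies |
| failure rates (p_drop, p_late) | 0.039 / 0.025 | — | reference sensing-failure mix used in the evaluation experiments |

All times are integer milliseconds on a single hub clock; in replay mode the
event payload timestamps drive the clock, so transport delay is excluded
from the user's measured execution time by construction.

## Numerical and semantic choices

- **Closed deadline boundary.** Coaching fires when `clock >= deadline`.
  A target performed 1 ms before the deadline suppresses the prompt; an
  event arriving exactly at the deadline is processed after the prompt
  (clock advance precedes judgement), deterministically.
- **Batch replay** visits every coaching deadline that falls strictly
  before the next event, so prompts are logged at their deadlines rather
  than at the next event's arrival.
- **Out-of-order events** (timestamp behind the clock) are judged without
  moving the clock, with a warning; unknown sensors and type-mismatched
  raw values are dropped with a warning and never touch engine state.
- **Abnormal behavior does not reset the timeout timer.** The timeout
  conditions reference only the previous step's completion and the
  previous coaching time, so abnormal and timeout coaching run on
  independent timers. Performing a future step's target early is abnormal
  (scenario-related but not the current target); it does not complete that
  step out of order.
- **Hysteresis** guarantees at most one state flip per monotone wattage
  ramp (verified by property test), preventing chattering near thresholds.
- **T3 measurement.** The repeat-coaching latency is measured from the
  engine-side time of the previous coaching (when the rule fired) to the
  delivery time of the repeat. Audio playback duration has no analogue in
  this artifact, so "previous coaching ended" reduces to "previous coaching
  fired"; with that convention T2 − limit and T3 − limit equal exactly the
  configured delivery latency, and 0 under an instantaneous sink.
- **T_act averaging.** T_act.avg defaults to the mean of per-behavior
  means (each unit-behavior weighted equally); pooling all trials instead
  is available via `t_act(..., over="trials")`. Behaviors with no
  recognized trial are excluded and surfaced to the caller.
- **Rounding.** Percentages are rounded half-up to one decimal, matching
  the report-table convention.

## What the simulator emulates — and what it does not

The simulator scripts a single virtual user per routine: perform the target
after a delay, perform a registered wrong action first, or idle past the
limit. It emits symbolic readings for contact/switch sensors and linear
wattage ramps for power devices, so the hysteresis device-state rules are
genuinely exercised; it injects sensing failures as one independent
categorical draw per scripted action (dropped, late by a configured amount,
or on time), each from an RNG sub-stream keyed by the action index so edits
to one action never perturb another's draws. Setup events before the
scenario start put devices into the states the script presumes (the
induction is switched on before the user is asked to switch it off).

It does **not** model physics, occupancy, sensor electronics, radio
transport, or burst/correlated failures (failures are independent by
assumption), and recognition gaps for binary sensors are exactly zero in
simulated time. Passing tests therefore demonstrate the correctness and
determinism of the inference and measurement pipeline under the stated
failure model — not the sensing accuracy of any physical deployment, whose
absolute latencies are dominated by hardware and network effects outside
this artifact's scope.

## Problem sizes

The test suite and `scripts/acceptance.py` use: exhaustive enumeration over
all (behavior × step) pairs of the 4-step scenario; ten seeded random
streams of 1000 events for engine-vs-reference equivalence; 10,010
simulated trials (11 unit-behaviors × 910) for failure-rate recovery, where
the binomial standard error of the rarest category is ~0.16 percentage
points; and 30 repetitions per routine for latency reporting. These sizes
make every statistical check tight while the whole suite runs in seconds.

## Known limitations

- Single-user hub: one active scenario at a time; no concurrent scenarios.
- No learning or adaptation of time limits; limits are static configuration.
- The live MQTT adapter is a thin untested shim (optional dependency); the
  replay path is the engineered, tested surface.
- Coaching message templates are English-only configuration defaults.
- A scenario only ends by completing all steps in order or by operator
  abort; there is no give-up-after-N-prompts policy beyond the repeat cap.
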