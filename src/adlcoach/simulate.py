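"""Discrete-event home simulator: a virtual user performing ADL scenarios.

This is the package's testbed.  A :class:`RoutineSpec` scripts what the
virtual user does at each step of a scenario — perform the target after a
delay, perform a wrong (abnormal) action first, or idle past the time
limit — and :func:`generate_stream` turns the script into the timestamped
sensor stream the ingestion layer consumes, together with a ground-truth
record of what was intended and when.

Realism choices:

* Contact/switch sensors emit a single symbolic reading; power-draw
  devices emit a linear wattage ramp (default 500 ms rise), so the
  hysteresis device-state rules are genuinely exercised and ON/OFF
  recognition lags the action, as it does with real appliance monitors.
* Sensing failures are modelled per scripted action as one categorical
  draw: with probability ``p_drop`` the reading never arrives (defective
  sensor / transport loss), with probability ``p_late`` it arrives
  ``late_extra_ms`` after the action (past the time limit); otherwise it
  is on time.  Draws are independent across actions, each from an RNG
  sub-stream keyed by the action index, so editing one action never
  perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    KnowledgeBase,
    LogEntry,
    SensorDescriptor,
    SensorEvent,
    load_knowledge_base,
)

__all__ = [
    "DEFAULT_KB_YAML",
    "UNIT_BEHAVIORS",
    "NoiseSpec",
    "StepAction",
    "RoutineSpec",
    "RoutineSpecError",
    "GroundTruthRecord",
    "default_knowledge_base",
    "builtin_routines",
    "generate_stream",
    "batch_trials",
    "run_recognition_experiment",
    "initial_state_for_trial",
]

#: Wattage ramp rise time for power devices (ms).
POWER_RISE_MS = 500
_POWER_SAMPLES = 5

#: The built-in deployment: a kitchen + living-room home with two scenarios.
DEFAULT_KB_YAML = """\
sensors:
  - {space: kitchen, sensor_type: door, states: [OPEN, CLOSED]}
  - {space: kitchen, sensor_type: window, states: [OPEN, CLOSED]}
  - {space: kitchen, sensor_type: refrigerator, states: [OPEN, CLOSED]}
  - {space: kitchen, sensor_type: light, states: [TURN_ON, TURN_OFF]}
  - {space: kitchen, sensor_type: induction, states: [TURN_ON, TURN_OFF],
     threshold: {"on": 50, "off": 10}}
  - {space: kitchen, sensor_type: hair_dryer, states: [TURN_ON, TURN_OFF],
     threshold: {"on": 50, "off": 10}}
  - {space: living_room, sensor_type: window, states: [OPEN, CLOSED]}
  - {space: living_room, sensor_type: air_conditioner, states: [TURN_ON, TURN_OFF]}
scenarios:
  - id: Scenario_1
    command: >-
      Turn off the induction and open the window in the kitchen, and get out.
    steps:
      - {space: kitchen, sensor_type: door, state: OPEN,
         coaching: Enter the kitchen.}
      - {space: kitchen, sensor_type: induction, state: TURN_OFF,
         coaching: Turn off the induction.}
      - {space: kitchen, sensor_type: window, state: OPEN,
         coaching: Open the window.}
      - {space: kitchen, sensor_type: door, state: CLOSED,
         coaching: Get out of the kitchen and close the door.}
    generals:
      - {space: kitchen, sensor_type: light, state: TURN_ON}
      - {space: kitchen, sensor_type: light, state: TURN_OFF}
    abnormals:
      - {space: kitchen, sensor_type: refrigerator, state: OPEN}
  - id: Scenario_2
    command: >-
      Close the window and turn on the air conditioner in the living room.
    steps:
      - {space: living_room, sensor_type: window, state: CLOSED,
         coaching: Close the living room window.}
      - {space: living_room, sensor_type: air_conditioner, state: TURN_ON,
         coaching: Turn on the air conditioner.}
users:
  - id: default
    default_limit_ms: 3000
  - id: slow_user
    default_limit_ms: 6000
    time_limits:
      Scenario_1: [6000, 8000, 6000, 6000]
"""

#: The deployment's distinct unit-behaviors (recognition experiments).
UNIT_BEHAVIORS: tuple[tuple[str, str, str], ...] = (
    ("kitchen", "door", "OPEN"),
    ("kitchen", "door", "CLOSED"),
    ("kitchen", "window", "OPEN"),
    ("kitchen", "window", "CLOSED"),
    ("kitchen", "refrigerator", "OPEN"),
    ("kitchen", "refrigerator", "CLOSED"),
    ("kitchen", "light", "TURN_ON"),
    ("kitchen", "induction", "TURN_ON"),
    ("kitchen", "induction", "TURN_OFF"),
    ("kitchen", "hair_dryer", "TURN_ON"),
    ("kitchen", "hair_dryer", "TURN_OFF"),
)


class RoutineSpecError(ValueError):
    """A routine references an unknown scenario/behavior or is malformed."""


def default_knowledge_base() -> KnowledgeBase:
    return load_knowledge_base(DEFAULT_KB_YAML)


@dataclass(frozen=True)
class NoiseSpec:
    """Per-action sensing-failure model (independent categorical draws)."""

    p_drop: float = 0.0
    p_late: float = 0.0
    late_extra_ms: int = 4000

    def __post_init__(self) -> None:
        if not (0 <= self.p_drop <= 1 and 0 <= self.p_late <= 1
                and self.p_drop + self.p_late <= 1):
            raise RoutineSpecError(f"invalid noise probabilities {self}")
        if self.late_extra_ms < 0:
            raise RoutineSpecError("late_extra_ms must be >= 0")


@dataclass(frozen=True)
class StepAction:
    """What the virtual user does during one step of a routine."""

    kind: str  # normal | abnormal | idle
    delay_ms: int = 1500
    behavior: tuple[str, str, str] | None = None
    recover_delay_ms: int = 1500
    duration_ms: int = 0

    @staticmethod
    def normal(delay_ms: int = 1500) -> "StepAction":
        """Perform the step's target ``delay_ms`` after the step opens."""
        return StepAction("normal", delay_ms=delay_ms)

    @staticmethod
    def abnormal(behavior: tuple[str, str, str], delay_ms: int = 1000,
                 recover_delay_ms: int = 1000) -> "StepAction":
        """Do a wrong action first, then the target after a recovery delay."""
        return StepAction("abnormal", delay_ms=delay_ms, behavior=behavior,
                          recover_delay_ms=recover_delay_ms)

    @staticmethod
    def idle(duration_ms: int) -> "StepAction":
        """Do nothing for ``duration_ms``, then perform the target."""
        return StepAction("idle", duration_ms=duration_ms)


@dataclass(frozen=True)
class RoutineSpec:
    """A scripted performance of one scenario by the virtual user."""

    scenario_id: str
    actions: tuple[StepAction, ...]
    user_id: str = "default"
    start_at: int = 5000
    seed: int = 0
    noise: NoiseSpec = field(default_factory=NoiseSpec)


@dataclass(frozen=True)
class GroundTruthRecord:
    """One scripted action: what was intended, and what actually went out."""

    action_index: int
    behavior: tuple[str, str, str]
    role: str  # target | abnormal
    step_no: int | None
    intended_time: int
    emitted_time: int | None  # None == DROPPED


def builtin_routines(limit_ms: int = 3000) -> dict[str, RoutineSpec]:
    """The four canonical test routines for Scenario_1.

    * ``normal`` — every step performed well within its limit; no coaching.
    * ``test_1`` — a wrong action (refrigerator opened) during step 2,
      corrected within the limit; exactly one abnormal coaching.
    * ``test_2`` — inactivity during step 3 past one time limit; exactly
      one timeout coaching.
    * ``test_3`` — the step-2 abnormality plus inactivity during step 4
      long enough for a first and a repeated timeout coaching.
    """
    wrong = ("kitchen", "refrigerator", "OPEN")
    L = limit_ms
    return {
        "normal": RoutineSpec("Scenario_1", tuple(StepAction.normal(L // 2)
                                                  for _ in range(4))),
        "test_1": RoutineSpec("Scenario_1", (
            StepAction.normal(L // 2),
            StepAction.abnormal(wrong, delay_ms=L // 3, recover_delay_ms=L // 3),
            StepAction.normal(L // 2),
            StepAction.normal(L // 2),
        )),
        "test_2": RoutineSpec("Scenario_1", (
            StepAction.normal(L // 2),
            StepAction.normal(L // 2),
            StepAction.idle(L + L // 3),
            StepAction.normal(L // 2),
        )),
        "test_3": RoutineSpec("Scenario_1", (
            StepAction.normal(L // 2),
            StepAction.abnormal(wrong, delay_ms=L // 3, recover_delay_ms=L // 3),
            StepAction.normal(L // 2),
            StepAction.idle(2 * L + L // 3),
        )),
    }


# ---------------------------------------------------------------------------
# Event emission


def _emit_action(descriptor: SensorDescriptor, state: str, t: int,
                 rise_ms: int = POWER_RISE_MS) -> list[SensorEvent]:
    """Events realizing one action: a symbol, or a wattage ramp."""
    if not descriptor.is_power:
        return [SensorEvent(descriptor.space, descriptor.sensor_type, state, t)]
    on_level = descriptor.threshold_on * 1.2
    start, end = (0.0, on_level) if state == descriptor.state_domain[0] else (on_level, 0.0)
    events = []
    for k in range(_POWER_SAMPLES):
        frac = k / (_POWER_SAMPLES - 1)
        events.append(
            SensorEvent(
                descriptor.space, descriptor.sensor_type,
                round(start + frac * (end - start), 3),
                t + round(frac * rise_ms),
            )
        )
    return events


def _action_end(descriptor: SensorDescriptor, t: int) -> int:
    return t + (POWER_RISE_MS if descriptor.is_power else 0)


def _noise_draw(rng: np.random.Generator, noise: NoiseSpec) -> tuple[bool, int]:
    """One categorical failure draw: (dropped?, extra delay ms)."""
    u = rng.random()
    if u < noise.p_drop:
        return True, 0
    if u < noise.p_drop + noise.p_late:
        return False, noise.late_extra_ms
    return False, 0


def generate_stream(
    routine: RoutineSpec, kb: KnowledgeBase
) -> tuple[list[SensorEvent], list[GroundTruthRecord]]:
    """Realize a routine as a time-sorted sensor stream plus ground truth.

    Setup events (e.g. switching on the induction the user will be asked to
    switch off) are emitted before the scenario starts so that every target
    is reachable by a real state change; they carry no ground-truth record.
    Identical ``(routine, seed)`` inputs give identical output.
    """
    if routine.scenario_id not in kb.scenarios:
        raise RoutineSpecError(
            f"unknown scenario {routine.scenario_id!r}; available: "
            f"{sorted(kb.scenarios)}"
        )
    scenario = kb.scenarios[routine.scenario_id]
    if len(routine.actions) != scenario.n_steps:
        raise RoutineSpecError(
            f"routine has {len(routine.actions)} actions but "
            f"{routine.scenario_id} has {scenario.n_steps} steps"
        )
    registered = {b.triple for b in
                  (*scenario.steps, *scenario.generals, *scenario.abnormals)}
    for a in routine.actions:
        if a.kind == "abnormal" and a.behavior not in registered:
            raise RoutineSpecError(
                f"abnormal action {a.behavior!r} is not registered to "
                f"{routine.scenario_id}"
            )

    events: list[SensorEvent] = []
    truth: list[GroundTruthRecord] = []

    # Setup phase: put any sensor whose first scripted state equals its
    # resting state into the opposite state before the scenario starts.
    first_state: dict[tuple[str, str], str] = {}
    for step in scenario.steps:
        first_state.setdefault((step.space, step.sensor_type), step.required_state)
    setup_t = routine.start_at - 2000
    for key, state in first_state.items():
        d = kb.sensors[key]
        if state == d.state_domain[-1]:  # already resting there: leave it
            other = d.state_domain[0]
            if d.is_power:
                events.append(SensorEvent(d.space, d.sensor_type,
                                          d.threshold_on * 1.2, setup_t))
            else:
                events.append(SensorEvent(d.space, d.sensor_type, other, setup_t))
            setup_t += 100

    action_idx = 0
    cursor = routine.start_at
    for step, action in zip(scenario.steps, routine.actions):
        descriptor = kb.sensors[(step.space, step.sensor_type)]
        scripted: list[tuple[tuple[str, str, str], str, int]] = []
        if action.kind == "normal":
            scripted.append((step.triple, "target", cursor + action.delay_ms))
        elif action.kind == "abnormal":
            ab_t = cursor + action.delay_ms
            scripted.append((action.behavior, "abnormal", ab_t))
            scripted.append((step.triple, "target", ab_t + action.recover_delay_ms))
        elif action.kind == "idle":
            scripted.append((step.triple, "target", cursor + action.duration_ms))
        else:
            raise RoutineSpecError(f"unknown action kind {action.kind!r}")
        for behavior, role, intended in scripted:
            rng = np.random.default_rng([abs(routine.seed), action_idx])
            dropped, extra = _noise_draw(rng, routine.noise)
            d = kb.sensors[(behavior[0], behavior[1])]
            if dropped:
                truth.append(GroundTruthRecord(action_idx, behavior, role,
                                               step.step_no if role == "target" else None,
                                               intended, None))
            else:
                emit_at = intended + extra
                events.extend(_emit_action(d, behavior[2], emit_at))
                truth.append(GroundTruthRecord(action_idx, behavior, role,
                                               step.step_no if role == "target" else None,
                                               intended, emit_at))
            action_idx += 1
        cursor = _action_end(descriptor, scripted[-1][2])

    events.sort(key=lambda e: e.hub_timestamp)
    return events, truth


def batch_trials(
    behavior: tuple[str, str, str],
    n_repeats: int,
    noise: NoiseSpec,
    seed: int,
    kb: KnowledgeBase | None = None,
    spacing_ms: int = 10_000,
    t0: int = 0,
) -> tuple[list[list[SensorEvent]], list[GroundTruthRecord]]:
    """Independent single-behavior trials for recognition-accuracy studies.

    Each trial performs ``behavior`` once from a fresh opposite prior state;
    trial ``i`` is scheduled at ``t0 + i*spacing_ms``.  Returns one event
    list per trial (empty when the reading was dropped) plus ground truth.
    """
    kb = kb if kb is not None else default_knowledge_base()
    descriptor = kb.sensor(behavior[0], behavior[1])
    if behavior[2] not in descriptor.state_domain:
        raise RoutineSpecError(f"state {behavior[2]!r} not in domain of "
                               f"{behavior[0]}/{behavior[1]}")
    trials: list[list[SensorEvent]] = []
    truth: list[GroundTruthRecord] = []
    for i in range(n_repeats):
        rng = np.random.default_rng([abs(seed), i])
        dropped, extra = _noise_draw(rng, noise)
        intended = t0 + i * spacing_ms
        if dropped:
            trials.append([])
            truth.append(GroundTruthRecord(i, behavior, "target", None, intended, None))
        else:
            trials.append(_emit_action(descriptor, behavior[2], intended + extra))
            truth.append(GroundTruthRecord(i, behavior, "target", None, intended,
                                           intended + extra))
    return trials, truth


def run_recognition_experiment(
    kb: KnowledgeBase,
    behaviors: Sequence[tuple[str, str, str]],
    n_per_behavior: int,
    noise: NoiseSpec,
    seed: int,
) -> tuple[list[GroundTruthRecord], list["LogEntry"]]:
    """Replay independent unit-behavior trials through the engine.

    Each trial runs on a fresh engine with the device pre-set to the
    opposite state, no scenario active, so every arriving reading surfaces
    as one ``behavior_observed`` log entry.  Trials are laid out on a
    shared timeline (behavior-major) so ground truth and logs can be
    matched unambiguously.  Returns the pooled ground truth and logs.
    """
    from .engine import CoachingEngine

    truth: list[GroundTruthRecord] = []
    logs: list[LogEntry] = []
    idx = 0
    for b_i, behavior in enumerate(behaviors):
        t0 = b_i * n_per_behavior * 10_000
        trials, gt = batch_trials(
            behavior, n_per_behavior, noise, seed=abs(seed) + b_i, kb=kb, t0=t0
        )
        initial = initial_state_for_trial(kb, behavior)
        for trial_events, rec in zip(trials, gt):
            engine = CoachingEngine(kb, "default")
            engine.sensors.reset(initial)
            for ev in trial_events:
                engine.process_event(ev)
            logs.extend(engine.transcript)
            truth.append(
                GroundTruthRecord(idx, rec.behavior, rec.role, rec.step_no,
                                  rec.intended_time, rec.emitted_time)
            )
            idx += 1
    return truth, logs


def initial_state_for_trial(
    kb: KnowledgeBase, behavior: tuple[str, str, str]
) -> dict[tuple[str, str], str]:
    """Prior device states so that performing ``behavior`` is a state change."""
    descriptor = kb.sensor(behavior[0], behavior[1])
    other = next(s for s in descriptor.state_domain if s != behavior[2])
    return {descriptor.key: other}
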