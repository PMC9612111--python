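"""Forward-chaining inference core for ADL scenario coaching.

The engine is a small production system in the CLIPS tradition: a working
memory of typed facts (sensor objects, the active scenario, per-step state,
the clock, and the append-only ADL_LOG) over which condition/action rule
units fire.  The agenda is deterministic — rules are examined in fixed
priority order (scenario end > behavior judging > timeout coaching), ties
broken by declaration order — so identical inputs always produce identical
logs.

Rule families
-------------
* **start / end rules** — activate a scenario, speak its command, detect
  that all steps are done in order, flush the log, and reset every
  scenario-scoped fact.
* **judge_user's_behavior** — on each sensor state change during an active
  scenario, classify the behavior as TARGET (completes the ongoing step),
  ABNORMAL (scenario-related but wrong → immediate corrective coaching), or
  GENERAL (expected background activity → recorded, nothing else).
* **coaching_now_step / coaching_again** — when the clock passes the
  ongoing step's per-user time limit (anchored at the previous step's
  completion, or the scenario start for step 1) a timeout prompt is spoken;
  while inactivity continues, the identical prompt repeats each further
  time-limit interval, anchored at the previous coaching.

Abnormal-behavior coaching and timeout coaching run on independent timers:
an abnormal action neither resets nor suppresses the pending timeout, since
the timeout conditions reference only the previous step's completion time
and the previous coaching time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Sequence

from .coaching import CoachingMessage, NullSink, SpeechSink, render_coaching
from .ingest import SensorStore, StateChange, TypeMismatchError
from .model import (
    Clock,
    KnowledgeBase,
    LogEntry,
    Scenario,
    SensorEvent,
    StepState,
    UnknownSensorError,
    UserProfile,
    validate_event,
)

__all__ = [
    "TARGET",
    "ABNORMAL",
    "GENERAL",
    "ScenarioBusyError",
    "NotFoundError",
    "ActiveScenario",
    "Fact",
    "FactStore",
    "CoachingEngine",
    "classify_behavior",
    "run_engine",
]

TARGET = "TARGET"
ABNORMAL = "ABNORMAL"
GENERAL = "GENERAL"


class ScenarioBusyError(RuntimeError):
    """A scenario is already active on this (single-user) hub."""


class NotFoundError(KeyError):
    """Unknown scenario or user id."""


@dataclass
class ActiveScenario:
    scenario_id: str
    user_id: str
    start_time: int


@dataclass(frozen=True)
class Fact:
    kind: str  # sensor | sensor_updated | scenario_active | step_state | adl_log | clock
    payload: Any


class FactStore:
    """Working memory: an ordered list of typed facts, queryable by kind."""

    def __init__(self) -> None:
        self._facts: list[Fact] = []

    def assert_fact(self, kind: str, payload: Any) -> Fact:
        f = Fact(kind, payload)
        self._facts.append(f)
        return f

    def retract(self, fact: Fact) -> None:
        self._facts.remove(fact)

    def by_kind(self, kind: str) -> list[Fact]:
        return [f for f in self._facts if f.kind == kind]

    def first(self, kind: str) -> Fact | None:
        for f in self._facts:
            if f.kind == kind:
                return f
        return None

    def __len__(self) -> int:
        return len(self._facts)


def classify_behavior(
    observed: tuple[str, str, str],
    scenario: Scenario,
    ongoing_step_no: int,
) -> str:
    """Classify one observed (space, sensor_type, state) during a scenario.

    TARGET if it matches the ongoing step's target triple; otherwise
    GENERAL if the scenario declares it as expected background activity;
    otherwise ABNORMAL if it matches any other behavior registered to the
    scenario (another step's target, or a declared known-wrong action);
    otherwise GENERAL — unregistered activity does not affect evaluation.
    """
    if observed == scenario.step(ongoing_step_no).triple:
        return TARGET
    if any(observed == g.triple for g in scenario.generals):
        return GENERAL
    for no, step in enumerate(scenario.steps, start=1):
        if no != ongoing_step_no and observed == step.triple:
            return ABNORMAL
    if any(observed == b.triple for b in scenario.abnormals):
        return ABNORMAL
    return GENERAL


@dataclass
class _Rule:
    name: str
    priority: int
    condition: Callable[[], Any]
    action: Callable[[Any], None]


class CoachingEngine:
    """Single-user e-coaching hub: sensors in, coaching and ADL_LOG out.

    Parameters
    ----------
    kb : KnowledgeBase
        Validated sensors, scenarios, and user profiles.
    user_id : str
        Whose time limits apply.
    sink : SpeechSink
        Where coaching messages are delivered (null by default; delivery is
        a side channel and never feeds back into engine state).
    max_coaching_repeats : int
        Upper bound on timeout prompts per step, so an unattended run
        terminates.
    """

    def __init__(
        self,
        kb: KnowledgeBase,
        user_id: str,
        sink: SpeechSink | None = None,
        max_coaching_repeats: int = 10,
    ) -> None:
        if user_id not in kb.users:
            raise NotFoundError(user_id)
        self.kb = kb
        self.user: UserProfile = kb.users[user_id]
        self.sink: SpeechSink = sink if sink is not None else NullSink()
        self.max_coaching_repeats = max_coaching_repeats
        self.clock = Clock(0)
        self.sensors = SensorStore(kb)
        self.facts = FactStore()
        self.transcript: list[LogEntry] = []
        self.flushed_logs: list[list[LogEntry]] = []
        self.warnings: list[str] = []
        for obj in self.sensors.objects.values():
            self.facts.assert_fact("sensor", obj)
        self.facts.assert_fact("clock", self.clock)
        # Deterministic agenda: priority desc, then declaration order.
        self._rules: list[_Rule] = [
            _Rule("end_scenario", 3, self._cond_end, self._act_end),
            _Rule("judge_user's_behavior", 2, self._cond_judge, self._act_judge),
            _Rule("coaching_now_step", 1, self._cond_coach_now, self._act_coach_now),
            _Rule("coaching_again", 1, self._cond_coach_again, self._act_coach_again),
        ]

    # -- queries ----------------------------------------------------------

    @property
    def active(self) -> ActiveScenario | None:
        f = self.facts.first("scenario_active")
        return f.payload if f else None

    @property
    def scenario(self) -> Scenario | None:
        a = self.active
        return self.kb.scenarios[a.scenario_id] if a else None

    def step_states(self) -> list[StepState]:
        return sorted(
            (f.payload for f in self.facts.by_kind("step_state")),
            key=lambda s: s.step_no,
        )

    def ongoing_step(self) -> StepState | None:
        for s in self.step_states():
            if s.status == "ongoing":
                return s
        return None

    def scenario_scoped_facts(self) -> list[Fact]:
        """Facts that must vanish when a scenario ends (reset completeness)."""
        return [
            f
            for f in self.facts._facts
            if f.kind in ("scenario_active", "step_state", "adl_log", "sensor_updated")
        ]

    def _anchor(self, step: StepState) -> int:
        """Timeout anchor: previous step's completion, or scenario start."""
        if step.step_no == 1:
            return self.active.start_time
        prev = next(s for s in self.step_states() if s.step_no == step.step_no - 1)
        return prev.done_time

    def _limit(self, step: StepState) -> int:
        return self.user.limit(step.scenario_id, step.step_no)

    def next_coaching_deadline(self) -> int | None:
        """Clock time at which the next timeout prompt is due, if any."""
        step = self.ongoing_step()
        if step is None or step.coaching_count >= self.max_coaching_repeats:
            return None
        if step.last_coaching_time is None:
            return self._anchor(step) + self._limit(step)
        return step.last_coaching_time + self._limit(step)

    # -- public API -------------------------------------------------------

    def start_scenario(self, scenario_id: str) -> None:
        """Activate a scenario: speak its command, open step 1, log the start."""
        if self.active is not None:
            raise ScenarioBusyError(self.active.scenario_id)
        if scenario_id not in self.kb.scenarios:
            raise NotFoundError(scenario_id)
        scenario = self.kb.scenarios[scenario_id]
        now = self.clock.now
        self.facts.assert_fact(
            "scenario_active", ActiveScenario(scenario_id, self.user.user_id, now)
        )
        for step in scenario.steps:
            st = StepState(scenario_id, step.step_no)
            if step.step_no == 1:
                st.status = "ongoing"
            self.facts.assert_fact("step_state", st)
        self._log(
            "scenario_start", scenario_id, None, {"user_id": self.user.user_id}
        )
        self._submit(
            CoachingMessage(scenario.command_text or f"Start {scenario_id}.",
                            "command", scenario_id, None, now)
        )
        self.run_cycle()

    def abort_scenario(self) -> None:
        """Operator abort: close the log and reset scenario-scoped facts."""
        a = self.active
        if a is None:
            return
        self._log("scenario_end", a.scenario_id, None, {"aborted": True})
        self._reset_scenario_facts()

    def advance_clock(self, t: int) -> None:
        """Move the clock forward to ``t`` and let time-based rules fire."""
        if self.clock.advance(t):
            self.run_cycle()

    def process_event(self, event: SensorEvent) -> None:
        """Validate, clock-advance, ingest, and run the match–fire loop."""
        try:
            validate_event(event, self.kb)
        except UnknownSensorError:
            self.warnings.append(
                f"unknown_sensor: {event.space}/{event.sensor_type} "
                f"at t={event.hub_timestamp} (event dropped)"
            )
            return
        if event.hub_timestamp < self.clock.now:
            self.warnings.append(
                f"out_of_order: event at t={event.hub_timestamp} behind clock "
                f"t={self.clock.now}; processed without moving the clock"
            )
        else:
            self.advance_clock(event.hub_timestamp)
        try:
            change = self.sensors.ingest_event(event)
        except TypeMismatchError as exc:
            self.warnings.append(f"type_mismatch: {exc} (event dropped)")
            return
        if change is None:
            return
        if self.active is None:
            self._log(
                "behavior_observed", None, None,
                {"classification": None, "observed": list(change[:3])},
            )
            return
        self.facts.assert_fact("sensor_updated", change)
        self.run_cycle()

    def run_cycle(self) -> None:
        """Match–fire until quiescent; first matching rule in agenda order fires."""
        while True:
            for rule in self._rules:
                match = rule.condition()
                if match is not None:
                    rule.action(match)
                    break
            else:
                return

    # -- rule units -------------------------------------------------------

    def _cond_end(self) -> Any:
        if self.active is None:
            return None
        steps = self.step_states()
        if steps and all(s.status == "done" for s in steps):
            times = [s.done_time for s in steps]
            if times == sorted(times):
                return steps
        return None

    def _act_end(self, steps: Sequence[StepState]) -> None:
        a = self.active
        now = self.clock.now
        self._log("scenario_end", a.scenario_id, None, {"end_time": now})
        self._submit(
            CoachingMessage(
                f"ADL evaluation for {a.scenario_id} is complete.",
                "end", a.scenario_id, None, now,
            )
        )
        self.flushed_logs.append(
            [f.payload for f in self.facts.by_kind("adl_log")]
        )
        self._reset_scenario_facts()

    def _cond_judge(self) -> Fact | None:
        if self.active is None:
            return None
        return self.facts.first("sensor_updated")

    def _act_judge(self, fact: Fact) -> None:
        change: StateChange = fact.payload
        self.facts.retract(fact)
        scenario = self.scenario
        step = self.ongoing_step()
        observed = (change.space, change.sensor_type, change.new_state)
        cls = classify_behavior(observed, scenario, step.step_no)
        now = self.clock.now
        if cls == TARGET:
            step.status = "done"
            step.done_time = now
            self._log(
                "step_done", scenario.scenario_id, step.step_no,
                {"classification": TARGET, "observed": list(observed)},
            )
            nxt = next(
                (s for s in self.step_states() if s.status == "pending"), None
            )
            if nxt is not None:
                nxt.status = "ongoing"
        elif cls == ABNORMAL:
            msg = render_coaching(scenario.step(step.step_no), observed, "abnormal", now)
            rec = self._submit(msg)
            self._log(
                "coaching", scenario.scenario_id, step.step_no,
                {
                    "classification": ABNORMAL, "reason": "abnormal",
                    "rule": "judge_user's_behavior", "observed": list(observed),
                    "text": msg.text, "delivered_at": rec.delivered_at,
                },
            )
        else:
            self._log(
                "behavior_observed", scenario.scenario_id, step.step_no,
                {"classification": GENERAL, "observed": list(observed)},
            )

    def _coaching_due(self, repeat: bool) -> StepState | None:
        step = self.ongoing_step()
        if step is None or step.coaching_count >= self.max_coaching_repeats:
            return None
        has_prior = step.last_coaching_time is not None
        if has_prior != repeat:
            return None
        anchor = step.last_coaching_time if repeat else self._anchor(step)
        if self.clock.now >= anchor + self._limit(step):
            return step
        return None

    def _cond_coach_now(self) -> StepState | None:
        return self._coaching_due(repeat=False)

    def _cond_coach_again(self) -> StepState | None:
        return self._coaching_due(repeat=True)

    def _act_coach_now(self, step: StepState) -> None:
        self._fire_timeout(step, "timeout", "coaching_now_step")

    def _act_coach_again(self, step: StepState) -> None:
        self._fire_timeout(step, "repeat_timeout", "coaching_again")

    def _fire_timeout(self, step: StepState, reason: str, rule: str) -> None:
        now = self.clock.now
        scenario = self.scenario
        msg = render_coaching(scenario.step(step.step_no), None, reason, now)
        rec = self._submit(msg)
        step.last_coaching_time = now
        step.coaching_count += 1
        self._log(
            "coaching", scenario.scenario_id, step.step_no,
            {
                "reason": reason, "rule": rule, "text": msg.text,
                "delivered_at": rec.delivered_at,
            },
        )

    # -- helpers ----------------------------------------------------------

    def _log(self, kind: str, scenario_id: str | None, step_no: int | None,
             detail: dict[str, Any]) -> LogEntry:
        entry = LogEntry(self.clock.now, kind, scenario_id, step_no, detail)
        self.transcript.append(entry)
        if self.active is not None or kind == "scenario_start":
            self.facts.assert_fact("adl_log", entry)
        return entry

    def _submit(self, message: CoachingMessage):
        from .coaching import DeliveryRecord

        try:
            return self.sink.submit(message)
        except Exception as exc:  # sink failure must not corrupt the scenario
            self.warnings.append(f"sink_failure: {exc!r}")
            return DeliveryRecord(message.issued_at, message.issued_at)

    def _reset_scenario_facts(self) -> None:
        for f in list(self.facts._facts):
            if f.kind in ("scenario_active", "step_state", "adl_log", "sensor_updated"):
                self.facts.retract(f)


def run_engine(
    events: Iterable[SensorEvent],
    kb: KnowledgeBase,
    user_id: str,
    scenario_plan: Sequence[tuple[int, str]],
    sink: SpeechSink | None = None,
    max_coaching_repeats: int = 10,
    until_ms: int | None = None,
) -> list[LogEntry]:
    """Replay a time-sorted event stream through the engine in batch.

    The clock advances to every scheduled scenario start and event
    timestamp, visiting each timeout-coaching deadline that falls strictly
    earlier first — prompts fire *at* the deadline, not at the next event.
    After the last event, any still-active scenario keeps accruing timeout
    prompts until the per-step repeat cutoff (or ``until_ms``) is reached.
    Deterministic: identical inputs yield identical logs.
    """
    engine = CoachingEngine(kb, user_id, sink, max_coaching_repeats)
    items: list[tuple[int, int, str, Any]] = [
        (t, 0, "start", sid) for t, sid in scenario_plan
    ] + [(e.hub_timestamp, 1, "event", e) for e in events]
    items.sort(key=lambda x: (x[0], x[1]))

    def drain_until(t: int | None) -> None:
        while True:
            d = engine.next_coaching_deadline()
            if d is None or (t is not None and d >= t):
                return
            engine.advance_clock(d)

    for t, _, kind, payload in items:
        drain_until(t)
        if kind == "start":
            engine.advance_clock(t)
            engine.start_scenario(payload)
        else:
            engine.process_event(payload)
    drain_until(until_ms + 1 if until_ms is not None else None)
    return engine.transcript
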