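"""Domain types and knowledge-base loading for ADL scenario coaching.

An ADL (activities-of-daily-living) scenario is a scripted everyday task
("turn off the induction and open the window in the kitchen, and get out")
decomposed into ordered *steps*, each completed by exactly one *target
behavior* — a (space, sensor_type, required_state) triple observable through
a smart-home sensor.  A knowledge base bundles the sensor inventory, the
scenarios, and per-user step time limits.

All times are integer milliseconds.  Step numbering is 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

__all__ = [
    "ABSENT",
    "Behavior",
    "Clock",
    "KnowledgeBase",
    "LogEntry",
    "Scenario",
    "SensorDescriptor",
    "SensorEvent",
    "SensorObject",
    "StepState",
    "UserProfile",
    "ValidationError",
    "UnknownSensorError",
    "load_knowledge_base",
    "dump_knowledge_base",
    "validate_event",
]

#: Step number sentinel for behaviors not tied to a step (general/abnormal).
ABSENT: None = None

#: Default per-step time limit (ms) when a user profile does not override it.
DEFAULT_TIME_LIMIT_MS = 3000


class ValidationError(ValueError):
    """A knowledge-base configuration violates a structural invariant."""


class UnknownSensorError(KeyError):
    """An event references a (space, sensor_type) pair not in the inventory."""


@dataclass(frozen=True)
class SensorDescriptor:
    """A deployed device: its unit-space, type, and discrete state domain.

    Power-draw devices (induction hob, hair dryer) additionally carry a
    hysteresis threshold pair; their discrete ON/OFF state is derived from
    the wattage by the device-state rules in :mod:`adlcoach.ingest`.
    """

    space: str
    sensor_type: str
    state_domain: tuple[str, ...]
    threshold_on: float | None = None
    threshold_off: float | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.space, self.sensor_type)

    @property
    def is_power(self) -> bool:
        return self.threshold_on is not None

    def __post_init__(self) -> None:
        if len(set(self.state_domain)) < 2:
            raise ValidationError(
                f"sensor {self.space}/{self.sensor_type}: state_domain needs "
                f"at least 2 distinct states, got {self.state_domain!r}"
            )
        if self.is_power and len(self.state_domain) != 2:
            raise ValidationError(
                f"power sensor {self.space}/{self.sensor_type} must have a "
                f"binary state domain (ON-like, OFF-like)"
            )


@dataclass(frozen=True)
class Behavior:
    """A unit-behavior: a sensor reaching a required state.

    ``kind`` distinguishes the three roles a behavior plays in a scenario:

    * ``target`` — completes the step ``step_no``;
    * ``general`` — expected household activity (light switching) that
      neither completes nor violates a step;
    * ``abnormal`` — a scenario-registered action that is never correct
      (opening the refrigerator mid-task) and triggers corrective coaching.
    """

    scenario_id: str
    space: str
    sensor_type: str
    required_state: str
    kind: str  # target | general | abnormal
    step_no: int | None = ABSENT
    coaching_message: str = ""

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.space, self.sensor_type, self.required_state)

    def describe(self) -> str:
        """Human phrase like ``'OPEN window'``."""
        return f"{self.required_state} {self.sensor_type}"

    def __post_init__(self) -> None:
        if self.kind not in ("target", "general", "abnormal"):
            raise ValidationError(f"behavior kind {self.kind!r} invalid")
        if (self.kind == "target") != (self.step_no is not ABSENT):
            raise ValidationError(
                f"behavior {self.describe()} in {self.scenario_id}: step_no "
                f"must be set iff kind='target'"
            )
        if self.kind == "target" and not self.coaching_message:
            raise ValidationError(
                f"target behavior {self.describe()} (step {self.step_no}) of "
                f"{self.scenario_id} has no coaching message"
            )


@dataclass(frozen=True)
class Scenario:
    """An ordered multi-step task plus its associated non-target behaviors."""

    scenario_id: str
    command_text: str
    steps: tuple[Behavior, ...]
    generals: tuple[Behavior, ...] = ()
    abnormals: tuple[Behavior, ...] = ()

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def step(self, step_no: int) -> Behavior:
        return self.steps[step_no - 1]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValidationError(f"scenario {self.scenario_id}: no steps")
        got = [b.step_no for b in self.steps]
        if got != list(range(1, len(self.steps) + 1)):
            raise ValidationError(
                f"scenario {self.scenario_id}: non-consecutive steps {got}"
            )
        for b in (*self.steps, *self.generals, *self.abnormals):
            if b.scenario_id != self.scenario_id:
                raise ValidationError(
                    f"behavior {b.describe()} carries scenario_id "
                    f"{b.scenario_id!r}, expected {self.scenario_id!r}"
                )


@dataclass(frozen=True)
class UserProfile:
    """Per-user step time limits, in ms, keyed by (scenario_id, step_no)."""

    user_id: str
    time_limits: Mapping[tuple[str, int], int] = field(default_factory=dict)
    default_limit_ms: int = DEFAULT_TIME_LIMIT_MS

    def limit(self, scenario_id: str, step_no: int) -> int:
        return int(self.time_limits.get((scenario_id, step_no), self.default_limit_ms))

    def __post_init__(self) -> None:
        for key, v in self.time_limits.items():
            if v <= 0:
                raise ValidationError(
                    f"user {self.user_id}: non-positive time limit {v} for {key}"
                )
        if self.default_limit_ms <= 0:
            raise ValidationError(f"user {self.user_id}: non-positive default limit")


@dataclass(frozen=True)
class SensorEvent:
    """One raw timestamped reading as published by an IoT device."""

    space: str
    sensor_type: str
    raw_value: float | str
    hub_timestamp: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "space": self.space,
                "sensor_type": self.sensor_type,
                "value": self.raw_value,
                "timestamp_ms": self.hub_timestamp,
            }
        )

    @classmethod
    def from_json(cls, line: str) -> "SensorEvent":
        d = json.loads(line)
        return cls(d["space"], d["sensor_type"], d["value"], int(d["timestamp_ms"]))


@dataclass
class SensorObject:
    """Current derived state of one device, updated by the object insertor."""

    space: str
    sensor_type: str
    state: str
    last_update: int = 0
    last_raw: float | str | None = None


@dataclass
class Clock:
    """Single source of truth for 'now' (ms); monotone non-decreasing."""

    now: int = 0

    def advance(self, t: int) -> bool:
        """Move to ``t`` if it is not in the past; return whether we moved."""
        if t < self.now:
            return False
        self.now = t
        return True


@dataclass
class StepState:
    """Mutable per-step progress while a scenario is active."""

    scenario_id: str
    step_no: int
    status: str = "pending"  # pending | ongoing | done
    done_time: int | None = None
    last_coaching_time: int | None = None
    coaching_count: int = 0


@dataclass(frozen=True)
class LogEntry:
    """One append-only ADL_LOG record; the unit all metrics are computed from."""

    timestamp: int
    entry_kind: str  # scenario_start | behavior_observed | step_done | coaching | scenario_end
    scenario_id: str | None
    step_no: int | None = None
    detail: Mapping[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "timestamp": self.timestamp,
                "entry_kind": self.entry_kind,
                "scenario_id": self.scenario_id,
                "step_no": self.step_no,
                "detail": dict(self.detail),
            }
        )

    @classmethod
    def from_json(cls, line: str) -> "LogEntry":
        d = json.loads(line)
        return cls(
            int(d["timestamp"]),
            d["entry_kind"],
            d.get("scenario_id"),
            d.get("step_no"),
            d.get("detail", {}),
        )


@dataclass(frozen=True)
class KnowledgeBase:
    """Validated sensors + scenarios + users for one deployment."""

    sensors: Mapping[tuple[str, str], SensorDescriptor]
    scenarios: Mapping[str, Scenario]
    users: Mapping[str, UserProfile]

    def sensor(self, space: str, sensor_type: str) -> SensorDescriptor:
        try:
            return self.sensors[(space, sensor_type)]
        except KeyError:
            raise UnknownSensorError(f"{space}/{sensor_type}") from None


# ---------------------------------------------------------------------------
# Loading / serialization


def _build_behavior(scenario_id: str, kind: str, raw: Mapping[str, Any],
                    step_no: int | None = None) -> Behavior:
    return Behavior(
        scenario_id=scenario_id,
        space=raw["space"],
        sensor_type=raw["sensor_type"],
        required_state=str(raw["state"]),
        kind=kind,
        step_no=step_no,
        coaching_message=raw.get("coaching", ""),
    )


def load_knowledge_base(source: str | Path | Mapping[str, Any]) -> KnowledgeBase:
    """Load and validate a knowledge base from YAML (path, text, or mapping).

    The document has three sections: ``sensors`` (the device inventory),
    ``scenarios`` (steps, generals, abnormals), and ``users`` (time limits).
    Loading is idempotent and rejects any configuration that violates a
    structural invariant, naming the offending object.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        text = Path(source).read_text() if (
            isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                         and Path(source).is_file())
        ) else str(source)
        doc = yaml.safe_load(text) or {}

    sensors: dict[tuple[str, str], SensorDescriptor] = {}
    for raw in doc.get("sensors", []) or []:
        thr = raw.get("threshold") or {}
        if isinstance(thr, (int, float)):
            thr = {"on": thr}
        # YAML 1.1 reads bare on/off keys as booleans; accept both spellings.
        thr = {
            ("on" if k is True else "off" if k is False else k): v
            for k, v in thr.items()
        }
        on = thr.get("on")
        desc = SensorDescriptor(
            space=raw["space"],
            sensor_type=raw["sensor_type"],
            state_domain=tuple(str(s) for s in raw["states"]),
            threshold_on=float(on) if on is not None else None,
            threshold_off=float(thr.get("off", on)) if on is not None else None,
        )
        if desc.key in sensors:
            raise ValidationError(
                f"duplicate sensor {desc.space}/{desc.sensor_type}"
            )
        sensors[desc.key] = desc

    scenarios: dict[str, Scenario] = {}
    for raw in doc.get("scenarios", []) or []:
        sid = raw["id"]
        steps = tuple(
            _build_behavior(sid, "target", b, step_no=i + 1)
            for i, b in enumerate(raw.get("steps", []) or [])
        )
        declared = [b.get("step") for b in (raw.get("steps", []) or []) if "step" in b]
        if declared and declared != list(range(1, len(steps) + 1)):
            raise ValidationError(f"scenario {sid}: non-consecutive steps {declared}")
        generals = tuple(
            _build_behavior(sid, "general", b) for b in raw.get("generals", []) or []
        )
        abnormals = tuple(
            _build_behavior(sid, "abnormal", b) for b in raw.get("abnormals", []) or []
        )
        scen = Scenario(sid, raw.get("command", ""), steps, generals, abnormals)
        if sid in scenarios:
            raise ValidationError(f"duplicate scenario id {sid!r}")
        for b in (*steps, *generals, *abnormals):
            key = (b.space, b.sensor_type)
            if key not in sensors:
                raise ValidationError(
                    f"behavior {b.describe()} (scenario {sid}) references "
                    f"missing sensor {b.space}/{b.sensor_type}"
                )
            if b.required_state not in sensors[key].state_domain:
                raise ValidationError(
                    f"behavior {b.describe()} (scenario {sid}): state "
                    f"{b.required_state!r} not in state domain "
                    f"{sensors[key].state_domain!r}"
                )
        scenarios[sid] = scen

    users: dict[str, UserProfile] = {}
    for raw in doc.get("users", []) or []:
        uid = raw["id"]
        limits: dict[tuple[str, int], int] = {}
        for sid, per_step in (raw.get("time_limits") or {}).items():
            if sid not in scenarios:
                raise ValidationError(
                    f"user {uid}: time limits for unknown scenario {sid!r}"
                )
            for i, ms in enumerate(per_step):
                limits[(sid, i + 1)] = int(ms)
        users[uid] = UserProfile(
            uid, limits, int(raw.get("default_limit_ms", DEFAULT_TIME_LIMIT_MS))
        )

    return KnowledgeBase(sensors, scenarios, users)


def dump_knowledge_base(kb: KnowledgeBase) -> str:
    """Serialize a knowledge base back to YAML; round-trips with the loader."""

    def behav(b: Behavior) -> dict[str, Any]:
        d: dict[str, Any] = {
            "space": b.space, "sensor_type": b.sensor_type, "state": b.required_state,
        }
        if b.coaching_message:
            d["coaching"] = b.coaching_message
        return d

    doc: dict[str, Any] = {"sensors": [], "scenarios": [], "users": []}
    for s in kb.sensors.values():
        raw: dict[str, Any] = {
            "space": s.space, "sensor_type": s.sensor_type,
            "states": list(s.state_domain),
        }
        if s.is_power:
            raw["threshold"] = {"on": s.threshold_on, "off": s.threshold_off}
        doc["sensors"].append(raw)
    for sc in kb.scenarios.values():
        doc["scenarios"].append(
            {
                "id": sc.scenario_id,
                "command": sc.command_text,
                "steps": [behav(b) for b in sc.steps],
                "generals": [behav(b) for b in sc.generals],
                "abnormals": [behav(b) for b in sc.abnormals],
            }
        )
    for u in kb.users.values():
        per: dict[str, list[int]] = {}
        for (sid, step_no), ms in sorted(u.time_limits.items()):
            per.setdefault(sid, []).append(ms)
        doc["users"].append(
            {"id": u.user_id, "time_limits": per, "default_limit_ms": u.default_limit_ms}
        )
    return yaml.safe_dump(doc, sort_keys=False)


def validate_event(event: SensorEvent, kb: KnowledgeBase) -> SensorEvent:
    """Pass through an event whose sensor is registered; reject otherwise.

    Raises :class:`UnknownSensorError` for unregistered (space, sensor_type)
    pairs; callers treat this as recoverable (drop + warn, engine unaffected).
    """
    kb.sensor(event.space, event.sensor_type)
    return event


def read_event_stream(path: str | Path) -> Iterable[tuple[int, SensorEvent | None, str]]:
    """Yield ``(lineno, event_or_None, raw_line)`` from a JSON-lines file.

    Malformed lines yield ``None`` so callers can warn and continue.
    """
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            yield i, SensorEvent.from_json(line), line
        except (json.JSONDecodeError, KeyError, TypeError, ValueError):
            yield i, None, line
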