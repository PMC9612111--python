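"""Sensor-event ingestion: topic parsing, device-state rules, object insertor.

IoT devices publish readings on MQTT-style topics of the form
``environment/sensor_space/sensor_type`` (e.g. ``home/room2/window``).  The
*device-state rules* turn raw readings into discrete device states: contact
and switch sensors report their state symbolically, while power-draw devices
report wattage that is thresholded with hysteresis (ON at or above
``threshold_on``, OFF at or below ``threshold_off``).  The *object insertor*
keeps one :class:`~adlcoach.model.SensorObject` per device and emits a
state-change notification to the inference engine only when the derived
state actually changed — repeated identical readings are debounced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .model import KnowledgeBase, SensorDescriptor, SensorEvent, SensorObject

__all__ = [
    "NO_CHANGE",
    "MalformedTopicError",
    "TypeMismatchError",
    "TopicInfo",
    "StateChange",
    "SensorStore",
    "parse_topic",
    "format_topic",
    "derive_device_state",
]


class MalformedTopicError(ValueError):
    """Topic does not have exactly three non-empty '/'-separated segments."""


class TypeMismatchError(TypeError):
    """Raw value class (numeric vs symbolic) does not fit the sensor class."""


class _NoChange:
    def __repr__(self) -> str:  # pragma: no cover
        return "NO_CHANGE"


#: Sentinel: the derived state equals the prior state; nothing to update.
NO_CHANGE = _NoChange()


class TopicInfo(NamedTuple):
    environment: str
    space: str
    sensor_type: str


def parse_topic(topic: str) -> TopicInfo:
    """Split ``environment/sensor_space/sensor_type`` into its segments."""
    parts = topic.split("/")
    if len(parts) != 3 or any(not p for p in parts):
        raise MalformedTopicError(topic)
    return TopicInfo(*parts)


def format_topic(info: TopicInfo) -> str:
    """Inverse of :func:`parse_topic`."""
    return f"{info.environment}/{info.space}/{info.sensor_type}"


def derive_device_state(
    descriptor: SensorDescriptor,
    raw_value: float | str,
    prior_state: str,
) -> str | _NoChange:
    """Apply the device-state rule for one reading.

    Symbolic sensors map the raw symbol to the state directly.  Power
    sensors compare wattage against the hysteresis pair: at or above
    ``threshold_on`` the device is ON (first state in the domain), at or
    below ``threshold_off`` it is OFF (second state); in between the prior
    state persists, which prevents chattering on gradual ramps.
    """
    if descriptor.is_power:
        if isinstance(raw_value, str):
            raise TypeMismatchError(
                f"{descriptor.space}/{descriptor.sensor_type}: power sensor "
                f"got symbolic value {raw_value!r}"
            )
        on_state, off_state = descriptor.state_domain[0], descriptor.state_domain[1]
        if raw_value >= descriptor.threshold_on:
            new = on_state
        elif raw_value <= descriptor.threshold_off:
            new = off_state
        else:
            new = prior_state
    else:
        if not isinstance(raw_value, str):
            raise TypeMismatchError(
                f"{descriptor.space}/{descriptor.sensor_type}: symbolic sensor "
                f"got numeric value {raw_value!r}"
            )
        if raw_value not in descriptor.state_domain:
            raise TypeMismatchError(
                f"{descriptor.space}/{descriptor.sensor_type}: value "
                f"{raw_value!r} outside state domain {descriptor.state_domain!r}"
            )
        new = raw_value
    return NO_CHANGE if new == prior_state else new


class StateChange(NamedTuple):
    """Notification that a device reached a new discrete state."""

    space: str
    sensor_type: str
    new_state: str
    timestamp: int


@dataclass
class SensorStore:
    """The object insertor: one mutable SensorObject per registered device.

    Devices start in their *resting* state — the last state in the domain
    (CLOSED for contact sensors, OFF for switches and power devices) —
    unless an explicit initial state is given.
    """

    kb: KnowledgeBase

    def __post_init__(self) -> None:
        self.objects: dict[tuple[str, str], SensorObject] = {}
        self.reset()

    def reset(self, initial: dict[tuple[str, str], str] | None = None) -> None:
        self.objects = {
            key: SensorObject(d.space, d.sensor_type,
                              (initial or {}).get(key, d.state_domain[-1]))
            for key, d in self.kb.sensors.items()
        }

    def ingest_event(self, event: SensorEvent) -> StateChange | None:
        """Update the sensor object; emit a StateChange iff the state changed."""
        descriptor = self.kb.sensor(event.space, event.sensor_type)
        obj = self.objects[descriptor.key]
        obj.last_raw = event.raw_value
        derived = derive_device_state(descriptor, event.raw_value, obj.state)
        if derived is NO_CHANGE:
            return None
        obj.state = derived
        obj.last_update = event.hub_timestamp
        return StateChange(event.space, event.sensor_type, derived, event.hub_timestamp)

    def snapshot(self) -> dict[tuple[str, str], tuple[str, int]]:
        return {k: (o.state, o.last_update) for k, o in self.objects.items()}
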