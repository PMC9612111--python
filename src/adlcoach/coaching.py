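"""Coaching messages and pluggable speech/text delivery sinks.

The inference engine decides *when* to coach; this module decides *what the
user hears* and hands it to a sink playing the role of the cloud
text-to-speech service.  Delivery is a side channel: engine state never
depends on which sink is configured, and a sink failure must not corrupt a
running scenario.  The fixed-latency sink exists to emulate a real TTS
round trip (about half a second for a cloud service) in latency studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

from .model import Behavior

__all__ = [
    "CoachingMessage",
    "DeliveryRecord",
    "SpeechSink",
    "NullSink",
    "RecordingSink",
    "FixedLatencySink",
    "render_coaching",
]


@dataclass(frozen=True)
class CoachingMessage:
    text: str
    reason: str  # abnormal | timeout | repeat_timeout | command | end
    scenario_id: str
    step_no: int | None
    issued_at: int

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("coaching message text must be non-empty")


@dataclass(frozen=True)
class DeliveryRecord:
    submitted_at: int
    delivered_at: int


class SpeechSink(Protocol):
    def submit(self, message: CoachingMessage) -> DeliveryRecord: ...


class NullSink:
    """Discards messages; delivery is instantaneous."""

    def submit(self, message: CoachingMessage) -> DeliveryRecord:
        return DeliveryRecord(message.issued_at, message.issued_at)


@dataclass
class RecordingSink:
    """Stores messages in submission order (the test double for TTS)."""

    messages: list[CoachingMessage] = field(default_factory=list)

    def submit(self, message: CoachingMessage) -> DeliveryRecord:
        self.messages.append(message)
        return DeliveryRecord(message.issued_at, message.issued_at)

    def dump_jsonl(self) -> str:
        import json

        return "\n".join(
            json.dumps(
                {
                    "text": m.text, "reason": m.reason, "scenario_id": m.scenario_id,
                    "step_no": m.step_no, "issued_at": m.issued_at,
                }
            )
            for m in self.messages
        )


@dataclass
class FixedLatencySink:
    """Reports delivery at submission + a configured latency (ms).

    Emulates the round trip to an external TTS service as a constant, so
    latency metrics can be studied without network or audio hardware.
    """

    latency_ms: int = 495
    messages: list[CoachingMessage] = field(default_factory=list)

    def submit(self, message: CoachingMessage) -> DeliveryRecord:
        self.messages.append(message)
        return DeliveryRecord(message.issued_at, message.issued_at + self.latency_ms)


def make_sink(spec: str) -> SpeechSink:
    """Build a sink from a CLI-style spec: ``null``, ``record``, ``latency:<ms>``."""
    if spec == "null":
        return NullSink()
    if spec == "record":
        return RecordingSink()
    if spec.startswith("latency:"):
        return FixedLatencySink(int(spec.split(":", 1)[1]))
    raise ValueError(f"unknown sink spec {spec!r}")


def render_coaching(
    ongoing: Behavior,
    observed: tuple[str, str, str] | None,
    reason: str,
    now: int,
) -> CoachingMessage:
    """Compose the message text for one coaching occasion.

    Timeout and repeated-timeout coaching use the step's stored instruction
    verbatim — repeats are intentionally byte-identical so the user hears
    the same content again.  Abnormal-behavior coaching prefixes a contrast
    clause naming what was observed versus the step's target.
    """
    stored = ongoing.coaching_message
    if reason in ("timeout", "repeat_timeout"):
        text = stored
    elif reason == "abnormal":
        obs = f"{observed[2]} {observed[1]}" if observed else "that"
        text = (
            f"You did '{obs}', but the target behavior is "
            f"'{ongoing.describe()}'. {stored}"
        )
    else:  # pragma: no cover - command/end rendered by the engine directly
        raise ValueError(f"render_coaching does not handle reason {reason!r}")
    return CoachingMessage(text, reason, ongoing.scenario_id, ongoing.step_no, now)
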