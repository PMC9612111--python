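"""Live MQTT adapter: subscribe to sensor topics and feed the engine.

Thin by design — the engine consumes only :class:`SensorEvent` objects, so
replay files fully substitute for a live broker and this adapter stays out
of the tested path.  Requires the optional ``paho-mqtt`` dependency
(``pip install adlcoach[mqtt]``).

Topic filter: ``environment/+/+``; payload: JSON ``{"value": ...,
"timestamp_ms": ...}``.
"""

from __future__ import annotations

import json

from .engine import CoachingEngine
from .ingest import MalformedTopicError, parse_topic
from .model import SensorEvent


def live_run(
    engine: CoachingEngine,
    broker_host: str,
    broker_port: int = 1883,
    environment: str = "home",
) -> None:
    """Subscribe to ``environment/+/+`` and process messages until interrupted."""
    try:
        import paho.mqtt.client as mqtt
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise RuntimeError(
            "live mode needs the optional dependency paho-mqtt "
            "(pip install adlcoach[mqtt]); use replay mode otherwise"
        ) from exc

    def on_message(client, userdata, msg):  # pragma: no cover - needs a broker
        try:
            info = parse_topic(msg.topic)
            payload = json.loads(msg.payload)
            event = SensorEvent(
                info.space, info.sensor_type,
                payload["value"], int(payload["timestamp_ms"]),
            )
        except (MalformedTopicError, json.JSONDecodeError, KeyError, ValueError) as e:
            engine.warnings.append(f"bad_message: {msg.topic}: {e}")
            return
        engine.process_event(event)

    client = mqtt.Client()  # pragma: no cover - needs a broker
    client.on_message = on_message
    client.connect(broker_host, broker_port)
    client.subscribe(f"{environment}/+/+")
    client.loop_forever()
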