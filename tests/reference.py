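"""Straight-line procedural reference interpreter for replay semantics.

An independent re-implementation of the coaching semantics as one
chronological scan with inline conditionals — no fact store, no rule
agenda, no match-fire loop.  Used as the oracle in engine-equivalence
tests: on identical inputs its (normalized) log must equal the rule
engine's entry for entry.
"""

from __future__ import annotations

from adlcoach.model import KnowledgeBase, LogEntry, SensorEvent


def normalize(entries: list[LogEntry]) -> list[tuple]:
    """Reduce log entries to comparable tuples."""
    out = []
    for e in entries:
        obs = e.detail.get("observed")
        out.append(
            (
                e.timestamp,
                e.entry_kind,
                e.scenario_id,
                e.step_no,
                e.detail.get("classification"),
                e.detail.get("reason"),
                tuple(obs) if obs else None,
            )
        )
    return out


def reference_run(
    events: list[SensorEvent],
    kb: KnowledgeBase,
    user_id: str,
    scenario_plan: list[tuple[int, str]],
    max_coaching_repeats: int = 10,
    until_ms: int | None = None,
) -> list[tuple]:
    """Sequential interpreter; returns the normalized log."""
    user = kb.users[user_id]
    sensor_state = {k: d.state_domain[-1] for k, d in kb.sensors.items()}
    log: list[tuple] = []

    clock = 0
    active: str | None = None
    start_time = 0
    ongoing = 0  # 1-based step number, 0 = none
    done_time: dict[int, int] = {}
    last_coaching: dict[int, int | None] = {}
    coach_count: dict[int, int] = {}

    def scenario():
        return kb.scenarios[active]

    def limit(step_no: int) -> int:
        return user.limit(active, step_no)

    def deadline() -> int | None:
        if active is None or ongoing == 0:
            return None
        if coach_count[ongoing] >= max_coaching_repeats:
            return None
        lc = last_coaching[ongoing]
        anchor = lc if lc is not None else (
            start_time if ongoing == 1 else done_time[ongoing - 1]
        )
        return anchor + limit(ongoing)

    def fire_timeout(at: int) -> None:
        nonlocal clock
        clock = max(clock, at)
        reason = "timeout" if last_coaching[ongoing] is None else "repeat_timeout"
        log.append((clock, "coaching", active, ongoing, None, reason, None))
        last_coaching[ongoing] = clock
        coach_count[ongoing] += 1

    def drain(bound: int | None) -> None:
        while True:
            d = deadline()
            if d is None or (bound is not None and d >= bound):
                return
            fire_timeout(d)

    def classify(obs: tuple[str, str, str]) -> str:
        sc = scenario()
        if obs == sc.steps[ongoing - 1].triple:
            return "TARGET"
        if any(obs == g.triple for g in sc.generals):
            return "GENERAL"
        for no, st in enumerate(sc.steps, start=1):
            if no != ongoing and obs == st.triple:
                return "ABNORMAL"
        if any(obs == b.triple for b in sc.abnormals):
            return "ABNORMAL"
        return "GENERAL"

    items = [(t, 0, sid) for t, sid in scenario_plan] + [
        (e.hub_timestamp, 1, e) for e in events
    ]
    items.sort(key=lambda x: (x[0], x[1]))

    for t, kind, payload in items:
        drain(t)
        if kind == 0:
            clock = max(clock, t)
            if active is not None:
                continue  # busy: the engine raises; plans in tests avoid this
            active = payload
            start_time = clock
            ongoing = 1
            done_time = {}
            n = scenario().n_steps
            last_coaching = {i: None for i in range(1, n + 1)}
            coach_count = {i: 0 for i in range(1, n + 1)}
            log.append((clock, "scenario_start", active, None, None, None, None))
            continue

        ev: SensorEvent = payload
        key = (ev.space, ev.sensor_type)
        if key not in kb.sensors:
            continue  # dropped before the clock moves
        if ev.hub_timestamp >= clock:
            clock = ev.hub_timestamp
            d = deadline()
            if d is not None and d <= clock:
                fire_timeout(d)
        descriptor = kb.sensors[key]
        prior = sensor_state[key]
        if descriptor.is_power:
            if isinstance(ev.raw_value, str):
                continue
            if ev.raw_value >= descriptor.threshold_on:
                new = descriptor.state_domain[0]
            elif ev.raw_value <= descriptor.threshold_off:
                new = descriptor.state_domain[1]
            else:
                new = prior
        else:
            if not isinstance(ev.raw_value, str) or (
                ev.raw_value not in descriptor.state_domain
            ):
                continue
            new = ev.raw_value
        if new == prior:
            continue
        sensor_state[key] = new
        obs = (ev.space, ev.sensor_type, new)
        if active is None:
            log.append((clock, "behavior_observed", None, None, None, None, obs))
            continue
        cls = classify(obs)
        if cls == "TARGET":
            done_time[ongoing] = clock
            log.append((clock, "step_done", active, ongoing, "TARGET", None, obs))
            if ongoing == scenario().n_steps:
                log.append((clock, "scenario_end", active, None, None, None, None))
                active = None
                ongoing = 0
            else:
                ongoing += 1
        elif cls == "ABNORMAL":
            log.append(
                (clock, "coaching", active, ongoing, "ABNORMAL", "abnormal", obs)
            )
        else:
            log.append(
                (clock, "behavior_observed", active, ongoing, "GENERAL", None, obs)
            )

    drain(until_ms + 1 if until_ms is not None else None)
    return log
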