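"""Discrete-event home simulator: determinism, noise rates, routine shapes."""

import numpy as np
import pytest

from adlcoach.engine import run_engine
from adlcoach.simulate import (
    UNIT_BEHAVIORS,
    NoiseSpec,
    RoutineSpec,
    RoutineSpecError,
    StepAction,
    batch_trials,
    generate_stream,
)


def replay(kb, routine, **kwargs):
    events, truth = generate_stream(routine, kb)
    logs = run_engine(events, kb, routine.user_id,
                      [(routine.start_at, routine.scenario_id)], **kwargs)
    return events, truth, logs


def coaching_reasons(logs):
    return [e.detail["reason"] for e in logs if e.entry_kind == "coaching"]


def test_streams_are_time_sorted_and_seed_deterministic(kb, routines):
    for r in routines.values():
        events, truth = generate_stream(r, kb)
        stamps = [e.hub_timestamp for e in events]
        assert stamps == sorted(stamps)
        events2, truth2 = generate_stream(r, kb)
        assert events == events2 and truth == truth2


def test_zero_noise_emission_times_equal_intended(kb, routines):
    _, truth = generate_stream(routines["normal"], kb)
    assert all(r.emitted_time == r.intended_time for r in truth)


def test_routine_must_match_scenario(kb):
    with pytest.raises(RoutineSpecError, match="unknown scenario"):
        generate_stream(RoutineSpec("Scenario_9", (StepAction.normal(),)), kb)
    with pytest.raises(RoutineSpecError, match="4 steps"):
        generate_stream(RoutineSpec("Scenario_1", (StepAction.normal(),)), kb)
    bad = RoutineSpec("Scenario_1", (
        StepAction.abnormal(("kitchen", "hair_dryer", "TURN_ON")),
        StepAction.normal(), StepAction.normal(), StepAction.normal(),
    ))
    with pytest.raises(RoutineSpecError, match="not registered"):
        generate_stream(bad, kb)


def test_setup_events_make_every_target_reachable(kb, routines):
    """The induction must be switched on before being asked to switch it off."""
    events, _, logs = replay(kb, routines["normal"])
    pre = [e for e in events if e.hub_timestamp < routines["normal"].start_at]
    assert any(e.sensor_type == "induction" for e in pre)
    assert sum(1 for e in logs if e.entry_kind == "step_done") == 4


def test_power_actions_are_ramps_exercising_hysteresis(kb, routines):
    events, truth, logs = replay(kb, routines["normal"])
    induction = [e for e in events
                 if e.sensor_type == "induction" and e.hub_timestamp >= 5000]
    assert len(induction) == 5  # linear ramp, not a single jump
    values = [e.raw_value for e in induction]
    assert values == sorted(values, reverse=True)  # switching off
    done2 = next(e for e in logs if e.entry_kind == "step_done" and e.step_no == 2)
    intended = next(r for r in truth if r.step_no == 2).intended_time
    assert 0 < done2.timestamp - intended <= 500  # recognized at the crossing


def test_dropped_actions_in_truth_but_not_stream(kb):
    r = RoutineSpec("Scenario_1", tuple(StepAction.normal() for _ in range(4)),
                    seed=5, noise=NoiseSpec(p_drop=0.5))
    events, truth = generate_stream(r, kb)
    dropped = [t for t in truth if t.emitted_time is None]
    assert dropped  # at seed 5, p=0.5, 4 actions: at least one drop expected
    assert len(truth) == 4
    for d in dropped:  # nothing was emitted at the dropped action's slot
        assert not any(e.sensor_type == d.behavior[1]
                       and e.hub_timestamp == d.intended_time for e in events)


def test_late_actions_shift_by_late_extra(kb):
    r = RoutineSpec("Scenario_1", tuple(StepAction.normal() for _ in range(4)),
                    seed=3, noise=NoiseSpec(p_late=1.0, late_extra_ms=4000))
    _, truth = generate_stream(r, kb)
    assert all(t.emitted_time == t.intended_time + 4000 for t in truth)


def test_drop_rate_converges_to_spec_at_large_n():
    """Law of large numbers: empirical drop fraction within 3 binomial SE."""
    p = 0.039
    n = 10_000
    trials, truth = batch_trials(("kitchen", "window", "OPEN"), n,
                                 NoiseSpec(p_drop=p), seed=11)
    frac = sum(1 for t in truth if t.emitted_time is None) / n
    se = np.sqrt(p * (1 - p) / n)
    assert abs(frac - p) <= 3 * se


def test_batch_trials_deterministic_and_empty(kb):
    a = batch_trials(UNIT_BEHAVIORS[0], 30, NoiseSpec(), seed=1, kb=kb)
    b = batch_trials(UNIT_BEHAVIORS[0], 30, NoiseSpec(), seed=1, kb=kb)
    assert a == b
    assert len(a[0]) == 30 and all(len(t) == 1 for t in a[0])
    empty_trials, empty_truth = batch_trials(UNIT_BEHAVIORS[0], 0, NoiseSpec(), seed=1)
    assert empty_trials == [] and empty_truth == []


def test_editing_one_action_leaves_earlier_draws_unchanged(kb):
    """Noise sub-streams are keyed per action, so a spec edit is local."""
    noise = NoiseSpec(p_drop=0.3)
    base = RoutineSpec("Scenario_1", tuple(StepAction.normal() for _ in range(4)),
                       seed=9, noise=noise)
    longer_idle = RoutineSpec(
        "Scenario_1",
        (*[StepAction.normal() for _ in range(3)], StepAction.idle(9000)),
        seed=9, noise=noise,
    )
    _, t1 = generate_stream(base, kb)
    _, t2 = generate_stream(longer_idle, kb)
    assert [(r.behavior, r.emitted_time is None) for r in t1[:3]] == [
        (r.behavior, r.emitted_time is None) for r in t2[:3]
    ]
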