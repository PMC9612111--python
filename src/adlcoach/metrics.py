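"""Evaluation metrics: recognition accuracy, recognition time, coaching latency.

Three families of quantities, all computed from ground truth (what the
virtual user actually did, and when) plus the engine's ADL_LOG:

* **Recognition categories** — each trial of a unit-behavior is either
  *recognized* (a matching log entry within the time limit), *incorrect
  sensing* (the reading never arrived), or *late* (recognized after the
  limit); the three counts partition the total.
* **Recognition time** — T_act, the per-behavior mean gap between the
  moment a behavior was performed and the moment the system logged it, and
  its overall average T_act.avg (by default the mean of the per-behavior
  means; averaging over all trials instead is available via ``over``).
* **Coaching latencies** — T1 (abnormal act → coaching heard), T2 (step
  start → first timeout coaching heard) and T3 (previous coaching → repeat
  coaching heard); T2 and T3 are reported net of the configured time limit,
  so in simulated time with an instantaneous sink they are exactly 0 and
  with a fixed-latency sink they equal the injected latency.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .model import LogEntry
from .simulate import GroundTruthRecord

__all__ = [
    "RecognitionSummary",
    "LatencyReport",
    "UndefinedRatioError",
    "match_recognition_times",
    "recognition_summary",
    "t_act",
    "coaching_latencies",
]


class UndefinedRatioError(ValueError):
    """Ratios over an empty ground truth are undefined."""


def _round1(x: float) -> float:
    """Half-up rounding to one decimal (table formatting convention)."""
    return float(Decimal(str(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RecognitionSummary:
    total: int
    recognized: int
    incorrect_sensing: int
    late: int

    @property
    def accuracy_pct(self) -> float:
        return _round1(100.0 * self.recognized / self.total)

    @property
    def incorrect_pct(self) -> float:
        return _round1(100.0 * self.incorrect_sensing / self.total)

    @property
    def late_pct(self) -> float:
        return _round1(100.0 * self.late / self.total)

    def __post_init__(self) -> None:
        if self.recognized + self.incorrect_sensing + self.late != self.total:
            raise ValueError("recognition categories must partition the total")

    def as_table(self, t_act_avg_ms: float | None = None) -> str:
        cols = [
            ("Total (Times)", self.total),
            ("Accurately Recognized (Times)", self.recognized),
            ("Tact.avg (ms)",
             "-" if t_act_avg_ms is None else round(t_act_avg_ms)),
            ("Ratio of Incorrect Sensing (%)", self.incorrect_pct),
            ("Ratio of Behavior Non-recognition within the Time Limit (%)",
             self.late_pct),
            ("Accuracy (%)", self.accuracy_pct),
        ]
        header = "\t".join(name for name, _ in cols)
        row = "\t".join(str(v) for _, v in cols)
        return f"{header}\n{row}"


@dataclass(frozen=True)
class LatencyReport:
    """Coaching latencies in ms; ``None`` marks a case absent from the routine."""

    t1_ms: float | None
    t2_minus_limit_ms: float | None
    t3_minus_limit_ms: float | None

    def as_row(self, name: str, executions: int | None = None) -> str:
        def fmt(v: float | None) -> str:
            return "-" if v is None else str(round(v))

        ex = "" if executions is None else f"\t{executions}"
        return (f"{name}{ex}\t{fmt(self.t1_ms)}\t{fmt(self.t2_minus_limit_ms)}"
                f"\t{fmt(self.t3_minus_limit_ms)}")


def _observed_triples(entry: LogEntry) -> tuple[str, str, str] | None:
    obs = entry.detail.get("observed")
    return tuple(obs) if obs else None


def match_recognition_times(
    ground_truth: list[GroundTruthRecord],
    logs: list[LogEntry],
) -> dict[int, int | None]:
    """For each ground-truth action, the log time it was recognized (or None).

    A recognition is the earliest log entry carrying an observed triple
    (``behavior_observed``, ``step_done``, or abnormal ``coaching``) that
    equals the action's behavior with a timestamp not before the action;
    each log entry matches at most one action,
    and the search window for an action closes when the next action with
    the same behavior is intended (so a lost reading cannot steal the
    following trial's recognition).
    """
    by_triple: dict[tuple[str, str, str], list[int]] = {}
    for e in logs:
        if e.entry_kind in ("behavior_observed", "step_done", "coaching"):
            obs = _observed_triples(e)
            if obs is not None:
                by_triple.setdefault(obs, []).append(e.timestamp)
    for times in by_triple.values():
        times.sort()
    ordered = sorted(ground_truth, key=lambda r: r.intended_time)
    next_intended: dict[int, int | None] = {}
    last_seen: dict[tuple[str, str, str], GroundTruthRecord] = {}
    for rec in ordered:
        prev = last_seen.get(rec.behavior)
        if prev is not None:
            next_intended[prev.action_index] = rec.intended_time
        last_seen[rec.behavior] = rec
    used: dict[tuple[str, str, str], int] = {}
    out: dict[int, int | None] = {}
    for rec in ordered:
        times = by_triple.get(rec.behavior, [])
        start = used.get(rec.behavior, 0)
        cutoff = next_intended.get(rec.action_index)
        found = None
        for j in range(start, len(times)):
            if times[j] >= rec.intended_time:
                if cutoff is None or times[j] < cutoff:
                    found = times[j]
                    used[rec.behavior] = j + 1
                break
        out[rec.action_index] = found
    return out


def recognition_summary(
    ground_truth: list[GroundTruthRecord],
    logs: list[LogEntry],
    time_limit_ms: int,
) -> RecognitionSummary:
    """Partition trials into recognized / incorrect-sensing / late."""
    if not ground_truth:
        raise UndefinedRatioError("empty ground truth")
    times = match_recognition_times(ground_truth, logs)
    recognized = incorrect = late = 0
    for rec in ground_truth:
        t = times[rec.action_index]
        if t is None:
            incorrect += 1
        elif t - rec.intended_time <= time_limit_ms:
            recognized += 1
        else:
            late += 1
    return RecognitionSummary(len(ground_truth), recognized, incorrect, late)


def t_act(
    ground_truth: list[GroundTruthRecord],
    logs: list[LogEntry],
    time_limit_ms: int | None = None,
    over: str = "behaviors",
) -> tuple[dict[tuple[str, str, str], float], float]:
    """Mean recognition gap per behavior, and the overall average.

    Only recognized trials enter the means; when ``time_limit_ms`` is given,
    trials recognized after the limit are excluded as well.  ``over``
    selects the overall average: ``"behaviors"`` (mean of the per-behavior
    means) or ``"trials"`` (mean over every recognized trial).  Behaviors
    with no recognized trial are excluded from the report.
    """
    if over not in ("behaviors", "trials"):
        raise ValueError(f"over must be 'behaviors' or 'trials', got {over!r}")
    times = match_recognition_times(ground_truth, logs)
    gaps: dict[tuple[str, str, str], list[int]] = {}
    for rec in ground_truth:
        t = times[rec.action_index]
        if t is None:
            continue
        gap = t - rec.intended_time
        if time_limit_ms is not None and gap > time_limit_ms:
            continue
        gaps.setdefault(rec.behavior, []).append(gap)
    per = {b: sum(g) / len(g) for b, g in gaps.items()}
    if not per:
        raise UndefinedRatioError("no recognized trials")
    if over == "behaviors":
        avg = sum(per.values()) / len(per)
    else:
        all_gaps = [g for gs in gaps.values() for g in gs]
        avg = sum(all_gaps) / len(all_gaps)
    return per, avg


def coaching_latencies(
    logs: list[LogEntry],
    time_limits: dict[int, int] | int,
) -> LatencyReport:
    """T1 / T2−limit / T3−limit from one scenario run's log.

    T1 uses the first abnormal coaching: delivery time minus the time of
    the offending act (the coaching entry's own timestamp, since abnormal
    coaching fires at the act).  T2 uses the first timeout coaching of a
    step: delivery time minus the step's start (the previous step's
    completion, or the scenario start).  T3 uses the first repeated
    coaching: delivery time minus the engine-side time of the previous
    coaching for that step.  ``time_limits`` maps step_no → limit ms (or a
    single int for all steps).  Absent cases are reported as ``None``.
    """

    def limit_for(step_no: int) -> int:
        if isinstance(time_limits, int):
            return time_limits
        return time_limits[step_no]

    start_time: int | None = None
    step_anchor: dict[int, int] = {}
    last_coaching: dict[int, int] = {}
    t1 = t2 = t3 = None
    for e in logs:
        if e.entry_kind == "scenario_start":
            start_time = e.timestamp
        elif e.entry_kind == "step_done":
            step_anchor[e.step_no + 1] = e.timestamp
        elif e.entry_kind == "coaching":
            reason = e.detail.get("reason")
            delivered = e.detail.get("delivered_at", e.timestamp)
            if reason == "abnormal":
                if t1 is None:
                    t1 = delivered - e.timestamp
            elif reason == "timeout":
                if t2 is None:
                    anchor = step_anchor.get(e.step_no, start_time)
                    t2 = delivered - anchor - limit_for(e.step_no)
                last_coaching[e.step_no] = e.timestamp
            elif reason == "repeat_timeout":
                if t3 is None and e.step_no in last_coaching:
                    t3 = delivered - last_coaching[e.step_no] - limit_for(e.step_no)
                last_coaching[e.step_no] = e.timestamp
    return LatencyReport(t1, t2, t3)
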