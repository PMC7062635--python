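"""Rule-based anomaly detection and self-healing.

A :class:`Rule` states a normal-operating-condition over windowed metric
aggregates ("mean cpu_load over 60 s must stay ≤ 0.95"), sustained for a
number of consecutive windows before an anomaly is raised.  Built-in
detectors cover the failure classes that a metric threshold cannot express:
runs that execute perpetually and never finish, hosts whose heartbeat went
silent, and a task scheduler that stopped dispatching while work is pending
and workers sit idle.

Healing maps each anomaly to its rule's single action — notify, restart the
offending workflow run (back to READY), restart the queue/dispatcher
service, or reboot the host — executed through a pluggable effector so the
same engine drives either the cluster simulator or a log-only notifier.
A per-(rule, subject) cooldown suppresses repeated restarts.
"""

from __future__ import annotations

import fnmatch
import json
import logging
import statistics
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Any, Iterable, Mapping, Protocol, Sequence

from opspilot.metrics_store import EmptyWindow, MetricsStore, aggregate
from opspilot.run_tracker import RunState, Tracker

logger = logging.getLogger(__name__)

ACTIONS = ("NOTIFY", "RESTART_WORKFLOW", "RESTART_SERVICE", "RESTART_VM")
COMPARATORS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    "≤": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "≥": lambda a, b: a >= b,
    "=": lambda a, b: a == b,
}

HEARTBEAT = "heartbeat"


@dataclass(frozen=True)
class Rule:
    """A normal-operating-condition contract over one metric selector.

    ``host_pattern`` is an fnmatch glob over host ids; the ``absence``
    aggregator fires on windows with no data and ignores comparator and
    threshold.  ``sustain_intervals`` consecutive breaching windows (each
    ``window_seconds`` long, ending at evaluation time) are required.
    """

    rule_id: str
    host_pattern: str
    metric_name: str
    window_seconds: float
    aggregator: str  # mean|max|min|last|count|absence
    comparator: str = ">"
    threshold: float = 0.0
    sustain_intervals: int = 1
    action: str = "NOTIFY"
    cooldown_seconds: float = 0.0

    def __post_init__(self) -> None:
        if self.sustain_intervals < 1:
            raise ValueError("sustain_intervals must be >= 1")
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.aggregator != "absence" and self.comparator not in COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "rule_id": self.rule_id,
            "host_pattern": self.host_pattern,
            "metric_name": self.metric_name,
            "window_seconds": self.window_seconds,
            "aggregator": self.aggregator,
            "comparator": self.comparator,
            "threshold": self.threshold,
            "sustain_intervals": self.sustain_intervals,
            "action": self.action,
            "cooldown_seconds": self.cooldown_seconds,
        }

    @classmethod
    def from_dict(cls, obj: Mapping[str, Any]) -> "Rule":
        return cls(**{k: obj[k] for k in cls.__dataclass_fields__ if k in obj})


def load_rules(path: str | Path) -> list[Rule]:
    with open(path) as fh:
        return [Rule.from_dict(obj) for obj in json.load(fh)]


@dataclass(frozen=True)
class AnomalyEvent:
    rule_id: str
    subject: str  # host_id or run_id
    detected_at: datetime
    evidence: tuple[float, ...] = ()
    action: str = "NOTIFY"

    def to_dict(self) -> dict[str, Any]:
        return {
            "rule_id": self.rule_id,
            "subject": self.subject,
            "detected_at": self.detected_at.isoformat(),
            "evidence": list(self.evidence),
            "action": self.action,
        }


@dataclass(frozen=True)
class HealingAction:
    anomaly: AnomalyEvent
    action: str
    executed_at: datetime
    outcome: str  # APPLIED | SUPPRESSED_COOLDOWN | NOTIFIED | FAILED

    def to_dict(self) -> dict[str, Any]:
        return {
            "rule_id": self.anomaly.rule_id,
            "subject": self.anomaly.subject,
            "action": self.action,
            "executed_at": self.executed_at.isoformat(),
            "outcome": self.outcome,
        }


# ---------------------------------------------------------------------------
# Detection


def evaluate_rules(
    rules: Sequence[Rule],
    store: MetricsStore,
    tracker: Tracker | None,
    now: datetime,
) -> list[AnomalyEvent]:
    """Evaluate every rule against the metric store at time ``now``.

    Pure: neither store nor tracker is mutated.  One event is emitted per
    (rule, subject) whose condition breached for ``sustain_intervals``
    consecutive windows ending at ``now``.
    """
    events: list[AnomalyEvent] = []
    for rule in rules:
        subjects = [
            h for h in store.hosts(rule.metric_name)
            if fnmatch.fnmatch(h, rule.host_pattern)
        ]
        if not subjects:
            logger.info("rule %s matched no subject", rule.rule_id)
            continue
        width = timedelta(seconds=rule.window_seconds)
        for host in subjects:
            evidence: list[float] = []
            breached = True
            for j in range(rule.sustain_intervals, 0, -1):
                win = store.window(
                    host, rule.metric_name, now - j * width, now - (j - 1) * width
                )
                if rule.aggregator == "absence":
                    n = len(win.samples)
                    if n > 0:
                        breached = False
                        break
                    evidence.append(0.0)
                    continue
                try:
                    value = aggregate(win, rule.aggregator)
                except EmptyWindow:
                    breached = False
                    break
                if not COMPARATORS[rule.comparator](value, rule.threshold):
                    breached = False
                    break
                evidence.append(value)
            if breached:
                events.append(
                    AnomalyEvent(
                        rule_id=rule.rule_id,
                        subject=host,
                        detected_at=now,
                        evidence=tuple(evidence),
                        action=rule.action,
                    )
                )
    return events


def _in_progress_since(run) -> datetime | None:
    for state, ts in reversed(run.history):
        if state is RunState.IN_PROGRESS:
            return ts
    return None


def _completed_stint_seconds(run) -> float | None:
    """Duration of the final IN_PROGRESS → COMPLETED stint, in seconds."""
    done = run.completed_at
    started = _in_progress_since(run)
    if done is None or started is None:
        return None
    return (done - started).total_seconds()


def detect_stuck_runs(
    tracker: Tracker,
    now: datetime,
    k: float = 3.0,
    floor_seconds: float = 600.0,
    action: str = "RESTART_WORKFLOW",
) -> list[AnomalyEvent]:
    """Flag runs IN_PROGRESS longer than max(floor, k × workflow median).

    The median is over completed-run durations of the same workflow; with no
    completed history the floor alone applies.  The floor keeps the first
    runs of a fresh workflow from flapping.
    """
    durations: dict[str, list[float]] = {}
    for run in tracker.runs.values():
        if run.state is RunState.COMPLETED:
            d = _completed_stint_seconds(run)
            if d is not None:
                durations.setdefault(run.workflow_id, []).append(d)
    events = []
    for run in sorted(tracker.runs.values(), key=lambda r: r.run_id):
        if run.state is not RunState.IN_PROGRESS:
            continue
        since = _in_progress_since(run)
        if since is None:
            continue
        elapsed = (now - since).total_seconds()
        completed = durations.get(run.workflow_id)
        threshold = floor_seconds
        if completed:
            threshold = max(floor_seconds, k * statistics.median(completed))
        if elapsed > threshold:
            events.append(
                AnomalyEvent(
                    rule_id="stuck-run",
                    subject=run.run_id,
                    detected_at=now,
                    evidence=(elapsed, threshold),
                    action=action,
                )
            )
    return events


def detect_unresponsive_hosts(
    store: MetricsStore,
    now: datetime,
    interval_seconds: float,
    missed: int = 3,
    action: str = "RESTART_VM",
) -> list[AnomalyEvent]:
    """Flag hosts whose last heartbeat is older than missed × interval.

    Hosts with no heartbeat history are never flagged: unknown ≠ crashed.
    """
    events = []
    for host in store.hosts(HEARTBEAT):
        last = store.last_timestamp(host, HEARTBEAT)
        if last is None:
            logger.info("host %s has no heartbeat history; skipping", host)
            continue
        silence = (now - last).total_seconds()
        if silence > missed * interval_seconds:
            events.append(
                AnomalyEvent(
                    rule_id="unresponsive-host",
                    subject=host,
                    detected_at=now,
                    evidence=(silence,),
                    action=action,
                )
            )
    return events


class QueueState(Protocol):
    """What the scheduler-failure detector needs from a task queue."""

    @property
    def pending_count(self) -> int: ...

    @property
    def idle_workers(self) -> int: ...

    @property
    def last_dispatch_at(self) -> datetime | None: ...


def detect_scheduler_failure(
    tracker: Tracker,
    queue_state: QueueState,
    now: datetime,
    stall_seconds: float,
    action: str = "RESTART_SERVICE",
) -> AnomalyEvent | None:
    """Detect a dispatcher stall: pending work, idle workers, no dispatch.

    All-busy workers are starvation, not scheduler failure; an empty queue
    is simply quiet.
    """
    if queue_state.pending_count <= 0 or queue_state.idle_workers <= 0:
        return None
    last = queue_state.last_dispatch_at
    stalled_for = float("inf") if last is None else (now - last).total_seconds()
    if stalled_for >= stall_seconds:
        return AnomalyEvent(
            rule_id="scheduler-failure",
            subject="scheduler",
            detected_at=now,
            evidence=(float(queue_state.pending_count), stalled_for),
            action=action,
        )
    return None


# ---------------------------------------------------------------------------
# Healing


class Effectors(Protocol):
    """Corrective-action backend (the simulator, or a log-only notifier)."""

    def restart_workflow(self, run_id: str, at: datetime) -> None: ...

    def restart_service(self, at: datetime) -> None: ...

    def restart_vm(self, host_id: str, at: datetime) -> None: ...

    def notify(self, event: AnomalyEvent) -> None: ...


class LogNotifier:
    """Default effector: everything is a log line; nothing is mutated."""

    def __init__(self) -> None:
        self.notified: list[AnomalyEvent] = []

    def restart_workflow(self, run_id: str, at: datetime) -> None:
        logger.warning("would restart workflow run %s", run_id)

    def restart_service(self, at: datetime) -> None:
        logger.warning("would restart queue dispatcher")

    def restart_vm(self, host_id: str, at: datetime) -> None:
        logger.warning("would restart VM %s", host_id)

    def notify(self, event: AnomalyEvent) -> None:
        self.notified.append(event)
        logger.warning("anomaly %s on %s", event.rule_id, event.subject)


def apply_healing(
    events: Iterable[AnomalyEvent],
    rules: Mapping[str, Rule] | Sequence[Rule],
    effectors: Effectors,
    now: datetime,
    history: list[HealingAction] | None = None,
) -> list[HealingAction]:
    """Execute each event's corrective action, honouring cooldowns.

    ``history`` holds prior actions (the caller keeps it across cycles);
    a second APPLIED action for the same (rule, subject) within the rule's
    cooldown window is recorded as SUPPRESSED_COOLDOWN instead.  Effector
    exceptions yield outcome FAILED and leave the anomaly open for the next
    cycle.  New actions are appended to ``history`` and returned.
    """
    if not isinstance(rules, Mapping):
        rules = {r.rule_id: r for r in rules}
    history = history if history is not None else []
    actions: list[HealingAction] = []
    for event in events:
        rule = rules.get(event.rule_id)
        action_name = rule.action if rule is not None else event.action
        cooldown = rule.cooldown_seconds if rule is not None else 0.0
        if action_name != "NOTIFY" and cooldown > 0:
            last_applied = [
                h.executed_at
                for h in history
                if h.outcome == "APPLIED"
                and h.anomaly.rule_id == event.rule_id
                and h.anomaly.subject == event.subject
            ]
            if last_applied and (now - max(last_applied)).total_seconds() < cooldown:
                actions.append(HealingAction(event, action_name, now, "SUPPRESSED_COOLDOWN"))
                continue
        try:
            if action_name == "NOTIFY":
                effectors.notify(event)
                outcome = "NOTIFIED"
            elif action_name == "RESTART_WORKFLOW":
                effectors.restart_workflow(event.subject, now)
                outcome = "APPLIED"
            elif action_name == "RESTART_SERVICE":
                effectors.restart_service(now)
                outcome = "APPLIED"
            elif action_name == "RESTART_VM":
                effectors.restart_vm(event.subject, now)
                outcome = "APPLIED"
            else:
                raise ValueError(f"unknown action {action_name!r}")
        except Exception:
            logger.exception("effector failed for %s on %s", action_name, event.subject)
            outcome = "FAILED"
        actions.append(HealingAction(event, action_name, now, outcome))
    history.extend(actions)
    return actions


@dataclass
class SentinelConfig:
    """Bundle of metric rules plus built-in detector parameters."""

    rules: list[Rule] = field(default_factory=list)
    stuck_k: float = 3.0
    stuck_floor_seconds: float = 600.0
    heartbeat_interval_seconds: float = 10.0
    heartbeat_missed: int = 3
    scheduler_stall_seconds: float = 120.0
    enable_stuck: bool = True
    enable_unresponsive: bool = True
    enable_scheduler: bool = True


def detect_all(
    config: SentinelConfig,
    store: MetricsStore,
    tracker: Tracker,
    queue_state: QueueState | None,
    now: datetime,
) -> list[AnomalyEvent]:
    """Run metric rules and every enabled built-in detector."""
    events = evaluate_rules(config.rules, store, tracker, now)
    if config.enable_stuck:
        events.extend(
            detect_stuck_runs(tracker, now, config.stuck_k, config.stuck_floor_seconds)
        )
    if config.enable_unresponsive:
        events.extend(
            detect_unresponsive_hosts(
                store, now, config.heartbeat_interval_seconds, config.heartbeat_missed
            )
        )
    if config.enable_scheduler and queue_state is not None:
        ev = detect_scheduler_failure(
            tracker, queue_state, now, config.scheduler_stall_seconds
        )
        if ev is not None:
            events.append(ev)
    return events
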