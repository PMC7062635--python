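"""Discrete-event simulation of a task-queue cluster, with fault injection.

The simulated cluster mirrors the architecture the package monitors: VM
profiles (workers plus dedicated queue/tracker hosts), a FIFO distributed
task queue from which workers pull one task per core, per-host metric
emission (heartbeat, cpu_load) at a fixed interval, and a fault plan that
injects the operational failure classes of interest — tasks that fail,
tasks that hang forever, VMs that crash mid-flight (stranding their tasks
in a perpetual IN_PROGRESS state), and a scheduler that stops dispatching.

When a sentinel configuration is supplied, anomaly detection runs every
metric interval on the simulated clock and its healing actions feed back
into the simulation (requeueing stuck work, rebooting hosts, unsticking the
dispatcher), so self-healing efficacy is directly measurable against the
same seed without healing.

Everything runs on a simulated clock; identical spec + seed gives a
bit-identical event log.  Randomness is split per concern (task durations,
fault fates, series jitter) by spawning child generators from the master
seed under fixed labels, so enabling faults does not perturb duration
draws.
"""

from __future__ import annotations

import heapq
import json
import math
from collections import deque
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from opspilot.metrics_store import MetricSample, MetricsStore
from opspilot.run_tracker import Analysis, RunState, Tracker, Workflow
from opspilot.sentinel import (
    AnomalyEvent,
    SentinelConfig,
    apply_healing,
    detect_all,
)

#: Fixed origin of the simulated clock.
EPOCH = datetime(2026, 1, 1, tzinfo=timezone.utc)

# Labels for per-concern RNG streams (stable across releases).
_RNG_DURATIONS = 1
_RNG_FAULTS = 2
_RNG_JITTER = 3
_RNG_METRICS = 4


def _rng(seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(label,)))


def sim_time(seconds: float) -> datetime:
    return EPOCH + timedelta(seconds=seconds)


# ---------------------------------------------------------------------------
# Specifications


@dataclass(frozen=True)
class Profile:
    name: str
    count: int
    cores: int
    roles: tuple[str, ...] = ("worker",)


@dataclass(frozen=True)
class ClusterSpec:
    """VM profiles plus the metric sampling interval.

    Exactly one profile must carry the ``queue`` role and one the
    ``tracker`` role (they may be the same profile).
    """

    profiles: tuple[Profile, ...]
    metric_interval_seconds: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(p.count < 0 for p in self.profiles):
            raise ValueError("profile count must be >= 0")
        for role in ("queue", "tracker"):
            holders = [p for p in self.profiles if role in p.roles]
            if len(holders) != 1:
                raise ValueError(f"exactly one profile must carry the {role!r} role")
        if self.metric_interval_seconds <= 0:
            raise ValueError("metric_interval_seconds must be positive")

    @classmethod
    def default(cls, n_workers: int = 4, cores: int = 2, seed: int = 0,
                metric_interval_seconds: float = 10.0) -> "ClusterSpec":
        return cls(
            profiles=(
                Profile("queue", 1, 2, ("queue",)),
                Profile("tracker", 1, 2, ("tracker",)),
                Profile("worker", n_workers, cores, ("worker",)),
            ),
            metric_interval_seconds=metric_interval_seconds,
            seed=seed,
        )

    def hosts(self) -> list[tuple[str, Profile]]:
        out = []
        for p in self.profiles:
            for i in range(p.count):
                out.append((f"{p.name}-{i}", p))
        return out

    def worker_hosts(self) -> list[tuple[str, int]]:
        return [(h, p.cores) for h, p in self.hosts() if "worker" in p.roles]


@dataclass(frozen=True)
class WorkloadSpec:
    """Samples to process and the task duration model.

    ``duration_model`` is ``lognormal`` (right-skewed, the shape typical of
    genomics task runtimes) with ``mu_log``/``sigma_log`` in log-seconds, or
    ``fixed`` with ``fixed_seconds``.
    """

    n_samples: int
    tasks_per_sample: int = 1
    duration_model: str = "lognormal"
    mu_log: float = 4.0
    sigma_log: float = 0.5
    fixed_seconds: float = 60.0
    max_attempts: int = 3
    workflow_name: str = "pipeline"

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if self.tasks_per_sample < 1:
            raise ValueError("tasks_per_sample must be >= 1")
        if self.duration_model not in ("lognormal", "fixed"):
            raise ValueError(f"unknown duration model {self.duration_model!r}")

    def draw_duration(self, rng: np.random.Generator) -> float:
        # always consumes one draw so fault toggles never shift the stream
        u = rng.standard_normal()
        if self.duration_model == "fixed":
            return self.fixed_seconds
        return float(np.exp(self.mu_log + self.sigma_log * u))


@dataclass(frozen=True)
class FaultPlan:
    """Injected failures: per-dispatch fates, VM crashes, scheduler hang."""

    task_failure_prob: float = 0.0
    stuck_task_prob: float = 0.0
    vm_crash_times: tuple[tuple[str, float], ...] = ()  # (host_id, seconds)
    scheduler_hang: tuple[float, float] | None = None  # (start_s, duration_s)

    def __post_init__(self) -> None:
        for p in (self.task_failure_prob, self.stuck_task_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("fault probabilities must lie in [0, 1]")

    @property
    def is_empty(self) -> bool:
        return (
            self.task_failure_prob == 0.0
            and self.stuck_task_prob == 0.0
            and not self.vm_crash_times
            and self.scheduler_hang is None
        )


@dataclass
class SimulationResult:
    event_log: list[dict[str, Any]]
    metrics: MetricsStore
    tracker: Tracker
    makespan_seconds: float | None
    horizon_reached: bool
    counts: dict[str, int]
    anomalies: list[AnomalyEvent] = field(default_factory=list)
    healing_log: list[Any] = field(default_factory=list)

    @property
    def completed_samples(self) -> int:
        return sum(
            1 for r in self.tracker.runs.values() if r.state is RunState.COMPLETED
        )

    def dump_event_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.event_log:
                fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# Engine internals


@dataclass
class _Task:
    run_id: str
    index: int  # step within the sample's task chain
    status: str = "queued"  # queued|running|completed|failed|stranded|cancelled
    host: str | None = None
    dispatch_version: int = 0


class _Queue:
    """FIFO pending-task queue; exposes the scheduler-failure view."""

    def __init__(self) -> None:
        self.pending: deque[str] = deque()
        self.last_dispatch_seconds: float | None = None
        self.hung: bool = False
        self._idle_workers: int = 0

    @property
    def pending_count(self) -> int:
        return len(self.pending)

    @property
    def idle_workers(self) -> int:
        return self._idle_workers

    @property
    def last_dispatch_at(self) -> datetime | None:
        if self.last_dispatch_seconds is None:
            return None
        return sim_time(self.last_dispatch_seconds)


class _Host:
    def __init__(self, host_id: str, cores: int) -> None:
        self.host_id = host_id
        self.cores = cores
        self.busy: dict[int, str] = {}  # core -> task_id
        self.crashed = False

    @property
    def idle_cores(self) -> int:
        return 0 if self.crashed else self.cores - len(self.busy)


class _Sim:
    def __init__(
        self,
        cluster: ClusterSpec,
        workload: WorkloadSpec,
        faults: FaultPlan,
        sentinel_config: SentinelConfig | None,
        horizon_seconds: float,
    ) -> None:
        self.cluster = cluster
        self.workload = workload
        self.faults = faults
        self.sentinel_config = sentinel_config
        self.horizon = horizon_seconds
        self.rng_dur = _rng(cluster.seed, _RNG_DURATIONS)
        self.rng_fault = _rng(cluster.seed, _RNG_FAULTS)

        self.now = 0.0
        self.heap: list[tuple[float, int, str, Any]] = []
        self.seq = 0
        self.log: list[dict[str, Any]] = []
        self.metrics = MetricsStore()
        self.tracker = Tracker()
        self.queue = _Queue()
        self.hosts = {h: _Host(h, p.cores) for h, p in cluster.hosts()}
        self.workers = {h: self.hosts[h] for h, _ in cluster.worker_hosts()}
        self.tasks: dict[str, _Task] = {}
        self.run_task_chain: dict[str, int] = {}  # run_id -> next task index
        self.counts = {
            "dispatched": 0, "completed_tasks": 0, "failed_tasks": 0,
            "stranded_tasks": 0, "cancelled_tasks": 0,
        }
        self.anomalies: list[AnomalyEvent] = []
        self.healing_log: list[Any] = []

    # -- event plumbing -----------------------------------------------------

    def push(self, t: float, kind: str, payload: Any = None) -> None:
        heapq.heappush(self.heap, (t, self.seq, kind, payload))
        self.seq += 1

    def record(self, kind: str, **fields: Any) -> None:
        self.log.append({"t": round(self.now, 6), "type": kind, **fields})

    # -- setup --------------------------------------------------------------

    def setup(self) -> None:
        wf = Workflow("wf-0", self.workload.workflow_name)
        self.tracker.register_workflow(wf)
        self.tracker.create_analysis(Analysis("an-0", "simulation", EPOCH))
        width = len(str(max(self.workload.n_samples, 1)))
        for i in range(self.workload.n_samples):
            run_id = f"run-{i:0{width}d}"
            self.tracker.create_run(run_id, "wf-0", "an-0", f"sample-{i:0{width}d}", EPOCH)
            self.run_task_chain[run_id] = 0
            self.enqueue_run(run_id, 0.0)
        interval = self.cluster.metric_interval_seconds
        n_ticks = int(math.floor(self.horizon / interval))
        for k in range(1, n_ticks + 1):
            self.push(k * interval, "tick")
        for host_id, t in self.faults.vm_crash_times:
            if t > self.horizon:
                raise ValueError("vm crash time beyond horizon")
            self.push(t, "crash", host_id)
        if self.faults.scheduler_hang is not None:
            start, duration = self.faults.scheduler_hang
            self.push(start, "hang_start")
            self.push(start + duration, "hang_end")
        self.emit_metrics()  # t = 0 baseline

    # -- queue / dispatch ---------------------------------------------------

    def enqueue_run(self, run_id: str, t: float) -> None:
        """Queue the run's next task and mark the run SCHEDULED."""
        index = self.run_task_chain[run_id]
        task_id = f"{run_id}/{index}/{self.tracker.runs[run_id].attempt_count}"
        self.tasks[task_id] = _Task(run_id=run_id, index=index)
        self.queue.pending.append(task_id)
        run = self.tracker.runs[run_id]
        if run.state is RunState.READY:
            self.tracker.transition(run_id, "schedule", sim_time(t))

    def dispatch(self) -> None:
        if self.queue.hung:
            return
        while self.queue.pending:
            slot = None
            for host_id in sorted(self.workers):
                host = self.workers[host_id]
                if host.idle_cores > 0:
                    core = next(c for c in range(host.cores) if c not in host.busy)
                    slot = (host, core)
                    break
            if slot is None:
                return
            task_id = self.queue.pending.popleft()
            task = self.tasks[task_id]
            host, core = slot
            task.status = "running"
            task.host = host.host_id
            task.dispatch_version += 1
            host.busy[core] = task_id
            self.counts["dispatched"] += 1
            self.queue.last_dispatch_seconds = self.now
            run = self.tracker.runs[task.run_id]
            if run.state is RunState.SCHEDULED:
                self.tracker.transition(task.run_id, "start", sim_time(self.now))
            duration = self.workload.draw_duration(self.rng_dur)
            fate = "ok"
            if not self.faults.is_empty:
                u = self.rng_fault.random()
                if u < self.faults.stuck_task_prob:
                    fate = "stuck"
                elif u < self.faults.stuck_task_prob + self.faults.task_failure_prob:
                    fate = "fail"
            self.record("dispatch", task=task_id, host=host.host_id, fate=fate,
                        duration=round(duration, 6))
            if fate != "stuck":
                self.push(
                    self.now + duration, "task_finish",
                    (task_id, task.dispatch_version, fate),
                )

    def free_core(self, task_id: str) -> None:
        task = self.tasks[task_id]
        if task.host is not None:
            host = self.hosts[task.host]
            for core, tid in list(host.busy.items()):
                if tid == task_id:
                    del host.busy[core]
        task.host = None

    # -- event handlers -----------------------------------------------------

    def on_task_finish(self, task_id: str, version: int, fate: str) -> None:
        task = self.tasks[task_id]
        if task.status != "running" or task.dispatch_version != version:
            return  # cancelled or requeued in the meantime
        self.free_core(task_id)
        run_id = task.run_id
        at = sim_time(self.now)
        if fate == "ok":
            task.status = "completed"
            self.counts["completed_tasks"] += 1
            self.record("task_complete", task=task_id)
            if task.index + 1 < self.workload.tasks_per_sample:
                self.run_task_chain[run_id] = task.index + 1
                index = self.run_task_chain[run_id]
                next_id = f"{run_id}/{index}/{self.tracker.runs[run_id].attempt_count}"
                self.tasks[next_id] = _Task(run_id=run_id, index=index)
                self.queue.pending.append(next_id)
            else:
                self.tracker.transition(run_id, "complete", at)
        else:  # fail
            task.status = "failed"
            self.counts["failed_tasks"] += 1
            self.record("task_fail", task=task_id)
            run = self.tracker.transition(run_id, "fail", at)
            if run.attempt_count < self.workload.max_attempts:
                self.tracker.transition(run_id, "retry", at)
                self.run_task_chain[run_id] = 0
                self.enqueue_run(run_id, self.now)

    def on_crash(self, host_id: str) -> None:
        host = self.hosts.get(host_id)
        if host is None or host.crashed:
            return
        host.crashed = True
        self.record("vm_crash", host=host_id)
        for core, task_id in list(host.busy.items()):
            task = self.tasks[task_id]
            task.status = "stranded"  # run stays IN_PROGRESS: never finishes
            self.counts["stranded_tasks"] += 1
            self.record("task_stranded", task=task_id, host=host_id)

    def emit_metrics(self) -> None:
        at = sim_time(self.now)
        for host_id, host in sorted(self.hosts.items()):
            if host.crashed:
                continue
            self.metrics.ingest(MetricSample(at, host_id, "heartbeat", 1.0))
            load = len(host.busy) / host.cores if host.cores else 0.0
            self.metrics.ingest(MetricSample(at, host_id, "cpu_load", load))

    def on_tick(self) -> None:
        self.emit_metrics()
        self.queue._idle_workers = sum(
            1 for h in self.workers.values() if h.idle_cores > 0
        )
        if self.sentinel_config is not None:
            events = detect_all(
                self.sentinel_config, self.metrics, self.tracker,
                self.queue, sim_time(self.now),
            )
            if events:
                self.anomalies.extend(events)
                for ev in events:
                    self.record("anomaly", rule=ev.rule_id, subject=ev.subject)
                actions = apply_healing(
                    events, self.sentinel_config.rules, _SimEffectors(self),
                    sim_time(self.now), history=self.healing_log,
                )
                for act in actions:
                    self.record(
                        "heal", rule=act.anomaly.rule_id,
                        subject=act.anomaly.subject, action=act.action,
                        outcome=act.outcome,
                    )

    # -- healing effectors (called via _SimEffectors) ------------------------

    def heal_restart_workflow(self, run_id: str) -> None:
        run = self.tracker.runs.get(run_id)
        if run is None or run.state is not RunState.IN_PROGRESS:
            return
        for task_id, task in self.tasks.items():
            if task.run_id == run_id and task.status in ("running", "stranded"):
                self.free_core(task_id)
                task.status = "cancelled"
                self.counts["cancelled_tasks"] += 1
            elif task.run_id == run_id and task.status == "queued":
                # drop a between-steps chain task so the restart is clean
                if task_id in self.queue.pending:
                    self.queue.pending.remove(task_id)
                task.status = "cancelled"
        at = sim_time(self.now)
        self.tracker.transition(run_id, "fail", at)
        self.tracker.transition(run_id, "retry", at)
        self.run_task_chain[run_id] = 0
        self.enqueue_run(run_id, self.now)

    def heal_restart_service(self) -> None:
        if self.queue.hung:
            self.queue.hung = False
            self.record("hang_cleared_by_heal")

    def heal_restart_vm(self, host_id: str) -> None:
        host = self.hosts.get(host_id)
        if host is None:
            return
        for core, task_id in list(host.busy.items()):
            task = self.tasks[task_id]
            if task.status == "running":
                task.status = "cancelled"
                self.counts["cancelled_tasks"] += 1
            run = self.tracker.runs[task.run_id]
            if run.state is RunState.IN_PROGRESS:
                at = sim_time(self.now)
                self.tracker.transition(task.run_id, "fail", at)
                self.tracker.transition(task.run_id, "retry", at)
                self.run_task_chain[task.run_id] = task.index
                self.enqueue_run(task.run_id, self.now)
            del host.busy[core]
        host.crashed = False
        self.record("vm_rebooted", host=host_id)

    # -- main loop ----------------------------------------------------------

    def run(self) -> SimulationResult:
        self.setup()
        self.dispatch()
        while self.heap:
            t, _, kind, payload = heapq.heappop(self.heap)
            if t > self.horizon:
                break
            self.now = t
            if kind == "task_finish":
                self.on_task_finish(*payload)
            elif kind == "tick":
                self.on_tick()
            elif kind == "crash":
                self.on_crash(payload)
            elif kind == "hang_start":
                self.queue.hung = True
                self.record("hang_start")
            elif kind == "hang_end":
                if self.queue.hung:
                    self.queue.hung = False
                    self.record("hang_end")
            self.dispatch()
        completed = [
            r for r in self.tracker.runs.values() if r.state is RunState.COMPLETED
        ]
        all_done = len(completed) == self.workload.n_samples
        if self.workload.n_samples == 0:
            makespan: float | None = 0.0
            horizon_reached = False
        elif all_done:
            makespan = max((r.completed_at - EPOCH).total_seconds() for r in completed)
            horizon_reached = False
        else:
            makespan = None
            horizon_reached = True
        tally: dict[str, int] = {}
        for task in self.tasks.values():
            tally[task.status] = tally.get(task.status, 0) + 1
        self.counts = {
            "dispatched": self.counts["dispatched"],
            "completed_tasks": tally.get("completed", 0),
            "failed_tasks": tally.get("failed", 0),
            "stranded_tasks": tally.get("stranded", 0),
            "cancelled_tasks": tally.get("cancelled", 0),
            "running_at_horizon": tally.get("running", 0),
            "still_queued": len(self.queue.pending),
        }
        return SimulationResult(
            event_log=self.log,
            metrics=self.metrics,
            tracker=self.tracker,
            makespan_seconds=makespan,
            horizon_reached=horizon_reached,
            counts=dict(self.counts),
            anomalies=self.anomalies,
            healing_log=self.healing_log,
        )


class _SimEffectors:
    """Bridge from sentinel healing actions into simulator state."""

    def __init__(self, sim: _Sim) -> None:
        self._sim = sim

    def restart_workflow(self, run_id: str, at: datetime) -> None:
        self._sim.heal_restart_workflow(run_id)

    def restart_service(self, at: datetime) -> None:
        self._sim.heal_restart_service()

    def restart_vm(self, host_id: str, at: datetime) -> None:
        self._sim.heal_restart_vm(host_id)

    def notify(self, event: AnomalyEvent) -> None:
        self._sim.record("notify", rule=event.rule_id, subject=event.subject)


def simulate(
    cluster: ClusterSpec,
    workload: WorkloadSpec,
    faults: FaultPlan | None = None,
    sentinel_config: SentinelConfig | None = None,
    horizon_seconds: float = 86_400.0,
) -> SimulationResult:
    """Run the cluster simulation to completion or to the horizon.

    Reaching the horizon with work outstanding flags the result
    (``horizon_reached``) rather than raising.  With a sentinel config,
    detection runs every metric interval and healing feeds back into the
    simulation.
    """
    if horizon_seconds <= 0:
        raise ValueError("horizon_seconds must be positive")
    faults = faults if faults is not None else FaultPlan()
    if sentinel_config is not None:
        # heartbeat cadence follows the cluster's metric interval
        sentinel_config = SentinelConfig(
            rules=sentinel_config.rules,
            stuck_k=sentinel_config.stuck_k,
            stuck_floor_seconds=sentinel_config.stuck_floor_seconds,
            heartbeat_interval_seconds=cluster.metric_interval_seconds,
            heartbeat_missed=sentinel_config.heartbeat_missed,
            scheduler_stall_seconds=sentinel_config.scheduler_stall_seconds,
            enable_stuck=sentinel_config.enable_stuck,
            enable_unresponsive=sentinel_config.enable_unresponsive,
            enable_scheduler=sentinel_config.enable_scheduler,
        )
    return _Sim(cluster, workload, faults, sentinel_config, horizon_seconds).run()


# ---------------------------------------------------------------------------
# Fixture generators


def generate_completion_series(
    n_samples: int,
    profile: str,
    profile_params: Mapping[str, Any] | None = None,
    seed: int = 0,
):
    """Synthesize a per-sample completion-timestamp series of a known shape.

    Profiles (times in arbitrary "units"; default total = ``n_samples``):

    - ``uniform``: equally spaced completions — the ideal diagonal.
    - ``stalled``: uniform progress with an idle gap of ``gap_fraction`` of
      the final total time inserted after ``stall_after`` of the samples.
    - ``bursty``: completions clustered just before each epoch in
      ``epochs`` (fractions of total time), mimicking batch uploads.

    ``jitter`` (fraction of the uniform spacing) adds seeded noise.
    """
    from opspilot.progress_analytics import CompletionSeries

    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    params = dict(profile_params or {})
    total = float(params.pop("total_time", float(n_samples)))
    jitter = float(params.pop("jitter", 0.0))
    i = np.arange(1, n_samples + 1, dtype=float)

    if profile == "uniform":
        times = total * i / n_samples
    elif profile == "stalled":
        g = float(params.pop("gap_fraction", 0.5))
        f = float(params.pop("stall_after", 0.5))
        if not 0.0 <= g < 1.0:
            raise ValueError("gap_fraction must lie in [0, 1)")
        work = total * (1.0 - g)
        gap = total * g
        times = work * i / n_samples
        k = int(round(f * n_samples))
        times[k:] += gap
    elif profile == "bursty":
        epochs = list(params.pop("epochs", (0.3, 0.6, 1.0)))
        span = float(params.pop("burst_span", 0.02)) * total
        groups = np.array_split(i, len(epochs))
        parts = []
        for epoch, group in zip(epochs, groups):
            end = epoch * total
            parts.append(end - span * (len(group) - np.arange(len(group))) / max(len(group), 1))
        times = np.concatenate(parts)
    else:
        raise ValueError(f"unknown completion profile {profile!r}")

    if params:
        raise ValueError(f"unknown profile parameters: {sorted(params)}")
    if jitter > 0:
        rng = _rng(seed, _RNG_JITTER)
        spacing = total / n_samples
        times = times + rng.uniform(-jitter * spacing, jitter * spacing, n_samples)
        times = np.sort(np.clip(times, spacing * 1e-3, None))
    return CompletionSeries(
        pipeline_name=profile,
        analysis_start=EPOCH,
        completions=tuple(sim_time(float(t)) for t in times),
    )


def generate_metric_stream(
    hosts: Sequence[str],
    interval_seconds: float,
    horizon_seconds: float,
    injections: Sequence[tuple[str, float, float]] = (),
    baseline: float = 0.30,
    noise: float = 0.05,
    anomaly_value: float = 1.6,
    metric_name: str = "cpu_load",
    heartbeat: bool = True,
    seed: int = 0,
) -> tuple[list[MetricSample], list[dict[str, Any]]]:
    """Emit a synthetic metric stream with labelled anomaly injections.

    Background values are ``baseline ± noise`` (uniform); during an
    injection window ``(host, start_s, duration_s)`` the host emits
    ``anomaly_value`` instead.  Returns the samples together with the
    injection log used as ground truth by detection-accuracy checks.
    """
    rng = _rng(seed, _RNG_METRICS)
    samples: list[MetricSample] = []
    log = [
        {"host": h, "start": s, "end": s + d, "metric": metric_name}
        for h, s, d in injections
    ]
    n_ticks = int(math.floor(horizon_seconds / interval_seconds)) + 1
    for k in range(n_ticks):
        t = k * interval_seconds
        at = sim_time(t)
        for host in hosts:
            value = baseline + rng.uniform(-noise, noise)
            for inj in log:
                if inj["host"] == host and inj["start"] <= t < inj["end"]:
                    value = anomaly_value
                    break
            samples.append(MetricSample(at, host, metric_name, float(value)))
            if heartbeat:
                samples.append(MetricSample(at, host, "heartbeat", 1.0))
    return samples, log
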