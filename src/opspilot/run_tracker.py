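"""Run lifecycle tracking and hierarchical configuration resolution.

The tracker is the system of record for workflow executions: each
:class:`AnalysisRun` is one execution of one workflow on one sample under one
analysis, moving through an explicit state machine
(``READY → SCHEDULED → IN_PROGRESS → COMPLETED``, with ``ERROR`` reachable
from any non-terminal state and recoverable only back to ``READY``).
Configuration is scoped at three levels of granularity — workflow, analysis
and run — and resolved at launch time into a single "effective
configuration", with more specific scopes overriding broader ones.

Persistence is a single-file SQLite store plus JSON export; completion
timestamps are exported as CSV for the progress-analytics layer.
"""

from __future__ import annotations

import copy
import csv
import json
import logging
import sqlite3
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Mapping

logger = logging.getLogger(__name__)


class RunState(str, Enum):
    READY = "READY"
    SCHEDULED = "SCHEDULED"
    IN_PROGRESS = "IN_PROGRESS"
    COMPLETED = "COMPLETED"
    ERROR = "ERROR"


class Scope(str, Enum):
    WORKFLOW = "WORKFLOW"
    ANALYSIS = "ANALYSIS"
    RUN = "RUN"


#: Legal (state, event) -> next-state table. COMPLETED is terminal.
TRANSITIONS: dict[tuple[RunState, str], RunState] = {
    (RunState.READY, "schedule"): RunState.SCHEDULED,
    (RunState.SCHEDULED, "start"): RunState.IN_PROGRESS,
    (RunState.IN_PROGRESS, "complete"): RunState.COMPLETED,
    (RunState.READY, "fail"): RunState.ERROR,
    (RunState.SCHEDULED, "fail"): RunState.ERROR,
    (RunState.IN_PROGRESS, "fail"): RunState.ERROR,
    (RunState.ERROR, "retry"): RunState.READY,
}

EVENTS = ("schedule", "start", "complete", "fail", "retry")


class IllegalTransition(ValueError):
    """Raised for an undefined (state, event) pair or a timestamp regression."""


def _utc(ts: datetime) -> datetime:
    if ts.tzinfo is None:
        return ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


@dataclass(frozen=True)
class Workflow:
    """A named, versioned pipeline definition. (name, version) is unique."""

    workflow_id: str
    name: str
    version: str = "1.0"


@dataclass(frozen=True)
class Analysis:
    """A campaign applying workflows to a sample cohort, anchored in time."""

    analysis_id: str
    name: str
    start_time: datetime

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_time", _utc(self.start_time))


@dataclass(frozen=True)
class AnalysisRun:
    """One execution of a workflow on one sample under one analysis.

    ``history`` is the ordered (state, timestamp) trail; ``attempt_count``
    equals 1 plus the number of ERROR→READY recoveries.
    """

    run_id: str
    workflow_id: str
    analysis_id: str
    sample_id: str
    state: RunState = RunState.READY
    history: tuple[tuple[RunState, datetime], ...] = ()
    attempt_count: int = 1

    def __post_init__(self) -> None:
        if not self.history:
            raise ValueError("history must contain at least the creation entry")

    @classmethod
    def create(
        cls,
        run_id: str,
        workflow_id: str,
        analysis_id: str,
        sample_id: str,
        at: datetime,
    ) -> "AnalysisRun":
        at = _utc(at)
        return cls(
            run_id=run_id,
            workflow_id=workflow_id,
            analysis_id=analysis_id,
            sample_id=sample_id,
            state=RunState.READY,
            history=((RunState.READY, at),),
            attempt_count=1,
        )

    @property
    def created_at(self) -> datetime:
        return self.history[0][1]

    @property
    def last_timestamp(self) -> datetime:
        return self.history[-1][1]

    @property
    def completed_at(self) -> datetime | None:
        """Timestamp of the final COMPLETED entry, or None."""
        for state, ts in reversed(self.history):
            if state is RunState.COMPLETED:
                return ts
        return None


def transition_run(run: AnalysisRun, event: str, at: datetime) -> AnalysisRun:
    """Apply a lifecycle event, returning a new run with updated history.

    Raises :class:`IllegalTransition` for an undefined (state, event) pair or
    a timestamp earlier than the last history entry.
    """
    if event not in EVENTS:
        raise IllegalTransition(f"unknown event {event!r}")
    at = _utc(at)
    key = (run.state, event)
    if key not in TRANSITIONS:
        raise IllegalTransition(
            f"event {event!r} is not legal in state {run.state.value}"
        )
    if at < run.last_timestamp:
        raise IllegalTransition(
            f"timestamp regression: {at.isoformat()} precedes "
            f"{run.last_timestamp.isoformat()}"
        )
    new_state = TRANSITIONS[key]
    attempts = run.attempt_count + (1 if event == "retry" else 0)
    return replace(
        run,
        state=new_state,
        history=run.history + ((new_state, at),),
        attempt_count=attempts,
    )


def replay_history(
    history: Iterable[tuple[RunState, datetime]],
) -> tuple[RunState, int]:
    """Recompute (final state, attempt_count) from a history trail.

    Used to audit stored runs: every adjacent pair must be a legal
    transition and timestamps must be non-decreasing.
    """
    items = list(history)
    state, _ = items[0]
    attempts = 1
    prev_ts = items[0][1]
    for nxt, ts in items[1:]:
        if ts < prev_ts:
            raise IllegalTransition("history timestamps regress")
        for (src, event), dst in TRANSITIONS.items():
            if src is state and dst is nxt:
                if event == "retry":
                    attempts += 1
                break
        else:
            raise IllegalTransition(f"no legal event takes {state} to {nxt}")
        state, prev_ts = nxt, ts
    return state, attempts


# ---------------------------------------------------------------------------
# Hierarchical configuration


@dataclass(frozen=True)
class ConfigurationLayer:
    """A parameter tree attached to one scope (workflow, analysis or run)."""

    scope: Scope
    subject_id: str
    tree: Mapping[str, Any] = field(default_factory=dict)

    @classmethod
    def from_json(cls, scope: Scope, subject_id: str, path: str | Path) -> "ConfigurationLayer":
        with open(path) as fh:
            return cls(scope=scope, subject_id=subject_id, tree=json.load(fh))

    @classmethod
    def empty(cls, scope: Scope) -> "ConfigurationLayer":
        return cls(scope=scope, subject_id="", tree={})


@dataclass(frozen=True)
class EffectiveConfiguration:
    """The merged parameter tree plus per-leaf provenance (winning scope)."""

    tree: dict[str, Any]
    provenance: dict[tuple[str, ...], Scope]


def _merge_into(
    tree: dict[str, Any],
    prov: dict[tuple[str, ...], Scope],
    layer_tree: Mapping[str, Any],
    scope: Scope,
    path: tuple[str, ...] = (),
) -> None:
    for key, value in layer_tree.items():
        kp = path + (key,)
        existing = tree.get(key)
        if isinstance(value, Mapping):
            if not isinstance(existing, dict):
                if key in tree and existing is not None:
                    logger.warning(
                        "config type conflict at %s: %s replaces scalar from "
                        "lower-precedence layer", ".".join(kp), scope.value,
                    )
                tree[key] = {}
                prov.pop(kp, None)
            _merge_into(tree[key], prov, value, scope, kp)
        else:
            if isinstance(existing, dict):
                logger.warning(
                    "config type conflict at %s: %s scalar replaces mapping "
                    "from lower-precedence layer", ".".join(kp), scope.value,
                )
                # drop provenance of the subtree being shadowed
                for stale in [p for p in prov if p[: len(kp)] == kp and p != kp]:
                    del prov[stale]
            tree[key] = copy.deepcopy(value)
            prov[kp] = scope


def resolve_effective_config(
    workflow_layer: ConfigurationLayer,
    analysis_layer: ConfigurationLayer,
    run_layer: ConfigurationLayer,
) -> EffectiveConfiguration:
    """Deep-merge the three scoped layers into an effective configuration.

    Precedence is RUN > ANALYSIS > WORKFLOW: the more specific scope
    overrides and augments the broader one at each key-path.  Mappings merge
    recursively; scalars and lists are replaced wholesale.  A type conflict
    (mapping vs scalar at the same path) resolves in favour of the
    higher-precedence layer with a logged warning.  An explicit null at a
    higher layer overrides (sets null) rather than deleting the key.
    """
    expected = (Scope.WORKFLOW, Scope.ANALYSIS, Scope.RUN)
    layers = (workflow_layer, analysis_layer, run_layer)
    for layer, scope in zip(layers, expected):
        if layer.scope is not scope:
            raise ValueError(f"layer {layer.scope} supplied where {scope} expected")
    tree: dict[str, Any] = {}
    prov: dict[tuple[str, ...], Scope] = {}
    for layer in layers:  # low to high precedence; later writes win
        _merge_into(tree, prov, layer.tree, layer.scope)
    return EffectiveConfiguration(tree=tree, provenance=prov)


# ---------------------------------------------------------------------------
# Tracker registry


class Tracker:
    """In-memory registry of workflows, analyses, runs and config layers.

    Offers SQLite persistence (:meth:`save` / :meth:`load`), JSON export of
    runs, and CSV export of completion-timestamp series for the analytics
    layer.
    """

    def __init__(self) -> None:
        self.workflows: dict[str, Workflow] = {}
        self.analyses: dict[str, Analysis] = {}
        self.runs: dict[str, AnalysisRun] = {}
        self.config_layers: dict[tuple[Scope, str], ConfigurationLayer] = {}

    # -- registration -------------------------------------------------------

    def register_workflow(self, workflow: Workflow) -> Workflow:
        for existing in self.workflows.values():
            if (existing.name, existing.version) == (workflow.name, workflow.version):
                raise ValueError(
                    f"workflow {workflow.name!r} version {workflow.version!r} "
                    "already registered"
                )
        self.workflows[workflow.workflow_id] = workflow
        return workflow

    def create_analysis(self, analysis: Analysis) -> Analysis:
        if analysis.analysis_id in self.analyses:
            raise ValueError(f"analysis {analysis.analysis_id!r} exists")
        self.analyses[analysis.analysis_id] = analysis
        return analysis

    def create_run(
        self,
        run_id: str,
        workflow_id: str,
        analysis_id: str,
        sample_id: str,
        at: datetime | None = None,
    ) -> AnalysisRun:
        if run_id in self.runs:
            raise ValueError(f"run {run_id!r} exists")
        if workflow_id not in self.workflows:
            raise KeyError(f"unknown workflow {workflow_id!r}")
        analysis = self.analyses.get(analysis_id)
        if analysis is None:
            raise KeyError(f"unknown analysis {analysis_id!r}")
        at = _utc(at) if at is not None else analysis.start_time
        if at < analysis.start_time:
            raise ValueError("run created before its analysis start_time")
        run = AnalysisRun.create(run_id, workflow_id, analysis_id, sample_id, at)
        self.runs[run_id] = run
        return run

    def transition(self, run_id: str, event: str, at: datetime) -> AnalysisRun:
        run = self.runs[run_id]
        updated = transition_run(run, event, at)
        self.runs[run_id] = updated
        return updated

    def set_config_layer(self, layer: ConfigurationLayer) -> None:
        self.config_layers[(layer.scope, layer.subject_id)] = layer

    def effective_config_for(self, run_id: str) -> EffectiveConfiguration:
        run = self.runs[run_id]
        wf = self.config_layers.get(
            (Scope.WORKFLOW, run.workflow_id), ConfigurationLayer.empty(Scope.WORKFLOW)
        )
        an = self.config_layers.get(
            (Scope.ANALYSIS, run.analysis_id), ConfigurationLayer.empty(Scope.ANALYSIS)
        )
        rn = self.config_layers.get(
            (Scope.RUN, run.run_id), ConfigurationLayer.empty(Scope.RUN)
        )
        return resolve_effective_config(wf, an, rn)

    # -- completion export --------------------------------------------------

    def completion_series(self, pipeline_name: str):
        """Sorted COMPLETED timestamps of a named pipeline, one per sample.

        A sample's completion is the timestamp of its final COMPLETED entry;
        earlier failed attempts contribute elapsed time implicitly.  Ties are
        broken by run_id so downstream binning is deterministic.
        """
        from opspilot.progress_analytics import CompletionSeries

        wf_ids = {w.workflow_id for w in self.workflows.values() if w.name == pipeline_name}
        if not wf_ids:
            raise KeyError(f"unknown pipeline {pipeline_name!r}")
        completed = [
            r for r in self.runs.values()
            if r.workflow_id in wf_ids and r.state is RunState.COMPLETED
        ]
        if not completed:
            raise ValueError(f"no completed runs for pipeline {pipeline_name!r}")
        completed.sort(key=lambda r: (r.completed_at, r.run_id))
        start = min(self.analyses[r.analysis_id].start_time for r in completed)
        return CompletionSeries(
            pipeline_name=pipeline_name,
            analysis_start=start,
            completions=tuple(r.completed_at for r in completed),
        )

    def export_completions_csv(self, path: str | Path, pipeline_names: Iterable[str] | None = None) -> None:
        """Write pipeline,sample_id,completed_at rows (ISO-8601 UTC)."""
        names = list(pipeline_names) if pipeline_names is not None else sorted(
            {w.name for w in self.workflows.values()}
        )
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["pipeline", "sample_id", "completed_at"])
            for name in names:
                wf_ids = {w.workflow_id for w in self.workflows.values() if w.name == name}
                rows = [
                    r for r in self.runs.values()
                    if r.workflow_id in wf_ids and r.state is RunState.COMPLETED
                ]
                rows.sort(key=lambda r: (r.completed_at, r.run_id))
                for r in rows:
                    writer.writerow([name, r.sample_id, r.completed_at.isoformat()])

    # -- JSON / SQLite persistence ------------------------------------------

    def export_runs_json(self, path: str | Path) -> None:
        payload = [
            {
                "run_id": r.run_id,
                "workflow_id": r.workflow_id,
                "analysis_id": r.analysis_id,
                "sample_id": r.sample_id,
                "state": r.state.value,
                "attempt_count": r.attempt_count,
                "history": [
                    {"state": s.value, "at": ts.isoformat()} for s, ts in r.history
                ],
            }
            for r in sorted(self.runs.values(), key=lambda r: r.run_id)
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    _SCHEMA = """
    CREATE TABLE IF NOT EXISTS workflows (
        workflow_id TEXT PRIMARY KEY, name TEXT, version TEXT,
        UNIQUE(name, version));
    CREATE TABLE IF NOT EXISTS analyses (
        analysis_id TEXT PRIMARY KEY, name TEXT, start_time TEXT);
    CREATE TABLE IF NOT EXISTS runs (
        run_id TEXT PRIMARY KEY, workflow_id TEXT, analysis_id TEXT,
        sample_id TEXT, state TEXT, attempt_count INTEGER);
    CREATE TABLE IF NOT EXISTS run_history (
        run_id TEXT, seq INTEGER, state TEXT, at TEXT,
        PRIMARY KEY(run_id, seq));
    CREATE TABLE IF NOT EXISTS config_layers (
        scope TEXT, subject_id TEXT, tree_json TEXT,
        PRIMARY KEY(scope, subject_id));
    """

    def save(self, path: str | Path) -> None:
        con = sqlite3.connect(str(path))
        try:
            con.executescript(self._SCHEMA)
            con.execute("DELETE FROM workflows")
            con.execute("DELETE FROM analyses")
            con.execute("DELETE FROM runs")
            con.execute("DELETE FROM run_history")
            con.execute("DELETE FROM config_layers")
            con.executemany(
                "INSERT INTO workflows VALUES (?,?,?)",
                [(w.workflow_id, w.name, w.version) for w in self.workflows.values()],
            )
            con.executemany(
                "INSERT INTO analyses VALUES (?,?,?)",
                [
                    (a.analysis_id, a.name, a.start_time.isoformat())
                    for a in self.analyses.values()
                ],
            )
            con.executemany(
                "INSERT INTO runs VALUES (?,?,?,?,?,?)",
                [
                    (r.run_id, r.workflow_id, r.analysis_id, r.sample_id,
                     r.state.value, r.attempt_count)
                    for r in self.runs.values()
                ],
            )
            con.executemany(
                "INSERT INTO run_history VALUES (?,?,?,?)",
                [
                    (r.run_id, i, s.value, ts.isoformat())
                    for r in self.runs.values()
                    for i, (s, ts) in enumerate(r.history)
                ],
            )
            con.executemany(
                "INSERT INTO config_layers VALUES (?,?,?)",
                [
                    (sc.value, sid, json.dumps(dict(layer.tree)))
                    for (sc, sid), layer in self.config_layers.items()
                ],
            )
            con.commit()
        finally:
            con.close()

    @classmethod
    def load(cls, path: str | Path) -> "Tracker":
        tracker = cls()
        con = sqlite3.connect(str(path))
        try:
            con.executescript(cls._SCHEMA)
            for wid, name, version in con.execute("SELECT * FROM workflows"):
                tracker.workflows[wid] = Workflow(wid, name, version)
            for aid, name, start in con.execute("SELECT * FROM analyses"):
                tracker.analyses[aid] = Analysis(aid, name, datetime.fromisoformat(start))
            hist: dict[str, list[tuple[RunState, datetime]]] = {}
            for rid, seq, state, at in con.execute(
                "SELECT run_id, seq, state, at FROM run_history ORDER BY run_id, seq"
            ):
                hist.setdefault(rid, []).append(
                    (RunState(state), datetime.fromisoformat(at))
                )
            for rid, wid, aid, sid, state, attempts in con.execute("SELECT * FROM runs"):
                tracker.runs[rid] = AnalysisRun(
                    run_id=rid, workflow_id=wid, analysis_id=aid, sample_id=sid,
                    state=RunState(state), history=tuple(hist[rid]),
                    attempt_count=attempts,
                )
            for sc, sid, tree_json in con.execute("SELECT * FROM config_layers"):
                tracker.config_layers[(Scope(sc), sid)] = ConfigurationLayer(
                    scope=Scope(sc), subject_id=sid, tree=json.loads(tree_json)
                )
        finally:
            con.close()
        return tracker
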