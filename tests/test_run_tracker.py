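"""Run state machine, hierarchical config resolution, completion export."""

from __future__ import annotations

import itertools
import json

import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from conftest import EPOCH, make_series, t
from opspilot.run_tracker import (
    EVENTS,
    TRANSITIONS,
    AnalysisRun,
    ConfigurationLayer,
    IllegalTransition,
    RunState,
    Scope,
    Tracker,
    Workflow,
    replay_history,
    resolve_effective_config,
    transition_run,
)


def fresh_run(run_id: str = "r1") -> AnalysisRun:
    return AnalysisRun.create(run_id, "wf-1", "an-1", "s1", EPOCH)


def drive(run: AnalysisRun, events: list[str]) -> AnalysisRun:
    for i, event in enumerate(events, start=1):
        run = transition_run(run, event, t(i))
    return run


class TestStateMachine:
    @pytest.mark.parametrize(
        "state,event", list(itertools.product(list(RunState), EVENTS))
    )
    def test_exhaustive_transition_table(self, state, event):
        """Every (state, event) pair behaves exactly per the lifecycle table."""
        paths = {
            RunState.READY: [],
            RunState.SCHEDULED: ["schedule"],
            RunState.IN_PROGRESS: ["schedule", "start"],
            RunState.COMPLETED: ["schedule", "start", "complete"],
            RunState.ERROR: ["fail"],
        }
        run = drive(fresh_run(), paths[state])
        assert run.state is state
        if (state, event) in TRANSITIONS:
            out = transition_run(run, event, t(10))
            assert out.state is TRANSITIONS[(state, event)]
            assert out.history[-1] == (out.state, t(10))
        else:
            with pytest.raises(IllegalTransition, match=event):
                transition_run(run, event, t(10))

    def test_completed_is_terminal(self):
        run = drive(fresh_run(), ["schedule", "start", "complete"])
        for event in EVENTS:
            with pytest.raises(IllegalTransition):
                transition_run(run, event, t(10))
        assert [s for s, _ in run.history].count(RunState.COMPLETED) == 1
        assert run.history[-1][0] is RunState.COMPLETED

    def test_retry_increments_attempt_count(self):
        run = drive(fresh_run(), ["schedule", "start", "fail", "retry"])
        assert run.state is RunState.READY
        assert run.attempt_count == 2

    def test_timestamp_regression_rejected(self):
        run = transition_run(fresh_run(), "schedule", t(100))
        with pytest.raises(IllegalTransition, match="regression"):
            transition_run(run, "start", t(50))

    def test_attempt_count_matches_error_ready_transitions(self):
        run = drive(
            fresh_run(),
            ["fail", "retry", "schedule", "fail", "retry", "schedule", "start",
             "complete"],
        )
        recoveries = sum(
            1
            for (a, _), (b, _) in zip(run.history, run.history[1:])
            if a is RunState.ERROR and b is RunState.READY
        )
        assert run.attempt_count == 1 + recoveries == 3

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.sampled_from(EVENTS), max_size=30), st.data())
    def test_replay_reproduces_state_and_rejects_illegal(self, events, data):
        """Replaying any legally built history reproduces the final state; a
        single illegal event injected anywhere is rejected."""
        run = fresh_run()
        clock = 0
        for event in events:
            clock += 1
            if (run.state, event) in TRANSITIONS:
                run = transition_run(run, event, t(clock))
            else:
                with pytest.raises(IllegalTransition):
                    transition_run(run, event, t(clock))
        state, attempts = replay_history(run.history)
        assert state is run.state
        assert attempts == run.attempt_count
        illegal = [e for e in EVENTS if (run.state, e) not in TRANSITIONS]
        if illegal:
            with pytest.raises(IllegalTransition):
                transition_run(run, data.draw(st.sampled_from(illegal)), t(clock + 1))


# ---------------------------------------------------------------------------


def layers(wf=None, an=None, rn=None):
    return (
        ConfigurationLayer(Scope.WORKFLOW, "w", wf or {}),
        ConfigurationLayer(Scope.ANALYSIS, "a", an or {}),
        ConfigurationLayer(Scope.RUN, "r", rn or {}),
    )


scalars = st.one_of(st.integers(-5, 5), st.booleans(), st.text(max_size=3), st.none())
trees = st.recursive(
    st.dictionaries(st.sampled_from("abcdef"), scalars, max_size=3),
    lambda children: st.dictionaries(
        st.sampled_from("abcdef"), st.one_of(scalars, children), max_size=3
    ),
    max_leaves=12,
)


class TestConfigResolution:
    def test_identity_under_empty_overrides(self):
        eff = resolve_effective_config(*layers(wf={"a": 1}))
        assert eff.tree == {"a": 1}
        assert eff.provenance == {("a",): Scope.WORKFLOW}

    def test_precedence_run_over_analysis_over_workflow(self):
        eff = resolve_effective_config(*layers(wf={"a": 1, "b": 2}, an={"b": 3}, rn={"c": 4}))
        assert eff.tree == {"a": 1, "b": 3, "c": 4}
        assert eff.provenance[("b",)] is Scope.ANALYSIS
        assert eff.provenance[("c",)] is Scope.RUN

    def test_nested_mappings_merge_recursively(self):
        # oracle: naive path-by-path recursive merge done by hand
        eff = resolve_effective_config(
            *layers(wf={"p": {"x": 1, "y": 2}}, an={"p": {"y": 9}})
        )
        assert eff.tree == {"p": {"x": 1, "y": 9}}
        assert eff.provenance[("p", "x")] is Scope.WORKFLOW
        assert eff.provenance[("p", "y")] is Scope.ANALYSIS

    def test_lists_replaced_wholesale(self):
        eff = resolve_effective_config(*layers(wf={"l": [1, 2]}, rn={"l": [9]}))
        assert eff.tree == {"l": [9]}

    def test_explicit_null_overrides(self):
        eff = resolve_effective_config(*layers(wf={"a": 1}, rn={"a": None}))
        assert eff.tree == {"a": None}
        assert eff.provenance[("a",)] is Scope.RUN

    def test_type_conflict_resolves_to_higher_precedence_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="opspilot.run_tracker"):
            eff = resolve_effective_config(
                *layers(wf={"p": {"x": 1}}, rn={"p": 7})
            )
        assert eff.tree == {"p": 7}
        assert eff.provenance == {("p",): Scope.RUN}
        assert any("conflict" in r.message for r in caplog.records)

    @settings(max_examples=60, derandomize=True,
              suppress_health_check=[HealthCheck.too_slow])
    @given(trees)
    def test_identity_and_idempotence(self, tree):
        eff = resolve_effective_config(*layers(wf=tree))
        assert eff.tree == tree
        again = resolve_effective_config(*layers(wf=eff.tree))
        assert again.tree == eff.tree

    @settings(max_examples=60, derandomize=True,
              suppress_health_check=[HealthCheck.too_slow])
    @given(trees, trees)
    def test_disjoint_key_sets_union(self, a, b):
        b = {k.upper(): v for k, v in b.items()}  # force disjoint top-level keys
        eff = resolve_effective_config(*layers(wf=a, rn=b))
        assert eff.tree == {**a, **b}

    @settings(max_examples=50, derandomize=True,
              suppress_health_check=[HealthCheck.too_slow])
    @given(trees, trees, trees)
    def test_every_leaf_has_exactly_one_provenance_entry(self, a, b, c):
        eff = resolve_effective_config(*layers(wf=a, an=b, rn=c))

        def leaves(node, path=()):
            for k, v in node.items():
                if isinstance(v, dict):
                    yield from leaves(v, path + (k,))
                else:
                    yield path + (k,)

        assert set(leaves(eff.tree)) == set(eff.provenance)


# ---------------------------------------------------------------------------


class TestTrackerRegistry:
    def test_duplicate_workflow_name_version_rejected(self, tracker):
        with pytest.raises(ValueError, match="already registered"):
            tracker.register_workflow(Workflow("wf-2", "freebayes", "1.0"))
        tracker.register_workflow(Workflow("wf-2", "freebayes", "2.0"))

    def test_completion_series_sorted_with_ties_by_run_id(self, tracker):
        for rid, done in [("r1", 1.0), ("r2", 3.0), ("r3", 2.0)]:
            tracker.create_run(rid, "wf-1", "an-1", f"s-{rid}")
            for event, at in [("schedule", 0), ("start", 0), ("complete", done)]:
                tracker.transition(rid, event, t(at))
        series = tracker.completion_series("freebayes")
        assert series.completions == (t(1), t(2), t(3))
        assert series.analysis_start == EPOCH

    def test_final_completion_wins_after_failed_attempts(self, tracker):
        tracker.create_run("r1", "wf-1", "an-1", "s1")
        for event, at in [("fail", 1), ("retry", 2), ("schedule", 3),
                          ("start", 4), ("complete", 7)]:
            tracker.transition("r1", event, t(at))
        series = tracker.completion_series("freebayes")
        assert series.completions == (t(7),)

    def test_in_progress_runs_excluded(self, tracker):
        tracker.create_run("r1", "wf-1", "an-1", "s1")
        for event, at in [("schedule", 0), ("start", 0), ("complete", 5)]:
            tracker.transition("r1", event, t(at))
        tracker.create_run("r2", "wf-1", "an-1", "s2")
        tracker.transition("r2", "schedule", t(0))
        tracker.transition("r2", "start", t(0))
        assert len(tracker.completion_series("freebayes")) == 1

    def test_unknown_pipeline_and_zero_completed_rejected(self, tracker):
        with pytest.raises(KeyError):
            tracker.completion_series("nope")
        tracker.create_run("r1", "wf-1", "an-1", "s1")
        with pytest.raises(ValueError, match="no completed runs"):
            tracker.completion_series("freebayes")

    def test_series_invariants(self, tracker):
        for i, done in enumerate([5.0, 1.0, 3.0, 3.0]):
            rid = f"r{i}"
            tracker.create_run(rid, "wf-1", "an-1", f"s{i}")
            for event, at in [("schedule", 0), ("start", 0), ("complete", done)]:
                tracker.transition(rid, event, t(at))
        series = tracker.completion_series("freebayes")
        assert list(series.completions) == sorted(series.completions)
        assert all(c >= series.analysis_start for c in series.completions)

    def test_sqlite_round_trip(self, tracker, tmp_path):
        tracker.create_run("r1", "wf-1", "an-1", "s1")
        tracker.transition("r1", "schedule", t(1))
        tracker.set_config_layer(
            ConfigurationLayer(Scope.WORKFLOW, "wf-1", {"ref": "GRCh37"})
        )
        db = tmp_path / "tracker.db"
        tracker.save(db)
        loaded = Tracker.load(db)
        assert loaded.runs["r1"] == tracker.runs["r1"]
        assert loaded.workflows == tracker.workflows
        assert loaded.analyses == tracker.analyses
        assert loaded.config_layers[(Scope.WORKFLOW, "wf-1")].tree == {"ref": "GRCh37"}

    def test_json_and_csv_export(self, tracker, tmp_path):
        tracker.create_run("r1", "wf-1", "an-1", "s1")
        for event, at in [("schedule", 0), ("start", 0), ("complete", 9)]:
            tracker.transition("r1", event, t(at))
        tracker.export_runs_json(tmp_path / "runs.json")
        runs = json.loads((tmp_path / "runs.json").read_text())
        assert runs[0]["state"] == "COMPLETED"
        assert runs[0]["history"][0]["state"] == "READY"
        tracker.export_completions_csv(tmp_path / "c.csv")
        lines = (tmp_path / "c.csv").read_text().strip().splitlines()
        assert lines[0] == "pipeline,sample_id,completed_at"
        assert lines[1].startswith("freebayes,s1,")

    def test_effective_config_for_run(self, tracker):
        tracker.create_run("r1", "wf-1", "an-1", "s1")
        tracker.set_config_layer(
            ConfigurationLayer(Scope.WORKFLOW, "wf-1", {"threads": 4, "ref": "x"})
        )
        tracker.set_config_layer(
            ConfigurationLayer(Scope.RUN, "r1", {"threads": 8})
        )
        eff = tracker.effective_config_for("r1")
        assert eff.tree == {"threads": 8, "ref": "x"}
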