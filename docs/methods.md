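# Methods

## Run lifecycle model

An `AnalysisRun` is one execution of one workflow on one sample under one
analysis. Its state machine is:

```
READY --schedule--> SCHEDULED --start--> IN_PROGRESS --complete--> COMPLETED
  |                    |                     |
  +-------fail---------+---------fail-------+----> ERROR --retry--> READY
```

`COMPLETED` is terminal. `SCHEDULED` is modelled as a distinct state
between `READY` and `IN_PROGRESS` because queueing and pickup are separate
observable moments in a task-queue architecture: a run can sit in the queue
arbitrarily long, and a scheduler stall is only diagnosable if that period
is distinguishable from execution. A `SCHEDULED` run may fail directly
(queue corruption, cancelled dispatch), so `fail` is legal from every
non-terminal state. Recovery from `ERROR` goes only to `READY` — a repaired
run re-enters the queue from the start; `attempt_count` is defined as
1 + the number of `ERROR→READY` transitions and is recomputable from the
history, which the audit helper `replay_history` exploits.

History timestamps are non-decreasing rather than strictly increasing:
automated fail-then-retry healing legitimately produces two entries at the
same instant.

## Configuration resolution

Configuration trees attach at three scopes — workflow, analysis, run — and
are deep-merged into an effective configuration with precedence
RUN > ANALYSIS > WORKFLOW. "More specific wins" is the only direction under
which a per-run parameter (say, a memory limit for one oversized sample)
can override fleet defaults. Mappings merge recursively; scalars and lists
are replaced wholesale (element-wise list merging has no sensible semantics
for command-line argument lists). Two deliberate edge rules:

- an explicit `null` at a higher scope *sets* null rather than deleting the
  key — deletion would make provenance ambiguous;
- a type conflict (mapping vs scalar at one path) resolves in favour of the
  higher-precedence layer and logs a warning, never errors: a run must not
  be blocked at launch time by a sloppy override.

Every leaf carries provenance (the winning scope), so an operator can ask
"where did this value come from" for any effective parameter.

## Metrics and anomaly rules

Metric samples are (host, metric, time, value) points; heartbeat is a
liveness convention (value 1 at each interval). All window queries are
half-open `[start, end)` so adjacent windows partition a series exactly —
no sample is double-counted when a rule walks consecutive windows.

A rule is a normal-operating-condition contract: aggregate (mean / max /
min / last / count / absence) over windows of `window_seconds`, compared
against a threshold, breached for `sustain_intervals` *consecutive* windows
ending at evaluation time. Sustain requirements are the debounce mechanism:
a single noisy window does not trigger a restart. The `absence` aggregator
fires on empty windows and ignores comparator and threshold. Evaluation is
pure; cadence is caller-driven (the simulator clock or a CLI replay), not
wall-clock, which keeps every test deterministic.

Three built-in detectors cover failures a metric threshold cannot express:

- **stuck runs** — IN_PROGRESS longer than
  `max(floor_seconds, k × median completed duration of the same workflow)`.
  Defaults `k = 3`, `floor_seconds = 600`. The multiple of the median (a
  robust location estimate for right-skewed task durations) adapts per
  workflow; the floor prevents flapping before a workflow has completed
  history. `k = 3` is a package default chosen as a conventional
  outlier-style cutoff; it is deliberately conservative because the healing
  action cancels real work.
- **unresponsive hosts** — last heartbeat older than `missed × interval`
  (default 3 missed beats). Hosts with no heartbeat history are never
  flagged: unknown is not crashed, and restart actions against unknown
  subjects would be unsafe.
- **scheduler failure** — pending tasks, at least one idle worker, and no
  dispatch for `stall_seconds`. All three conjuncts matter: a busy cluster
  with a full queue is starvation, not scheduler failure.

Healing maps each anomaly to its rule's single action (notify, restart
workflow / service / VM); there is no implicit escalation ladder, because
an escalation policy is an operator decision, not a detector property. A
per-(rule, subject) cooldown separates repeated restarts; suppressed and
failed executions are recorded (`SUPPRESSED_COOLDOWN`, `FAILED`) so an
anomaly left open is visible in the action log.

## Cluster simulator

A hand-written event-heap discrete-event engine (simulated clock, never
wall-clock). Workers pull tasks greedily from a FIFO queue, one task per
core, in deterministic host/core order. Task durations default to
lognormal (right-skewed, the empirical shape of genomics task runtimes;
`mu_log = 4.0`, `sigma_log = 0.5`, i.e. median ≈ 55 s at desk scale — shape
is the point, not fitted values). Fault classes:

- *failed tasks*: the run transitions to ERROR; the engine retries up to
  `max_attempts` (default 3);
- *stuck tasks*: never finish, occupying a core until healed — this is what
  makes "runs that never finish" observable;
- *VM crashes*: heartbeats stop and in-flight tasks are stranded with their
  runs left IN_PROGRESS — deliberately *not* transitioned to ERROR, because
  a crashed host cannot set a failed status; only heartbeat absence reveals
  it;
- *scheduler hang*: the dispatcher stops dispatching for an interval.

Randomness is split per concern (durations, fault fates, jitter, metric
noise) by spawning child generators from the master seed under fixed
labels, so toggling the fault plan does not perturb duration draws and
healed/unhealed comparisons are genuinely paired. Identical spec + seed
gives a bit-identical event log.

With a sentinel configuration, detection runs every metric interval and
healing feeds back: workflow restarts cancel the in-flight task and requeue
the run (fail → retry → schedule, so the tracker history stays legal), VM
reboots resume heartbeats and requeue stranded work, service restarts clear
a dispatcher hang.

### Fixture generators

`generate_completion_series` produces completion series of known shape for
the analytics layer: `uniform` (the ideal diagonal), `stalled` (an idle gap
of fraction *g* of the final total time inserted after fraction *f* of the
samples — constructively, the cumulative-time curve jumps `100·g·(1−f)`
percentage points above the diagonal at the stall, which is the expected
maximum uniformity deviation), and `bursty` (completions clustered at
epochs, mimicking batch uploads). `generate_metric_stream` emits
baseline-plus-noise metric values with labelled anomaly injections; the
injection log is the ground truth for detection precision/recall
experiments. Injected magnitudes (default 1.6 against a 0.8 threshold and
0.30 ± 0.05 background) are separated by construction, so exact
precision = recall = 1.0 is the correct expectation — the experiments
quantify the engine's bookkeeping, not threshold tuning on marginal
signals.

### What the simulator does not model

Network topology, storage contention, duration heterogeneity across
samples (beyond the lognormal draw), correlated failures, and cost. Green
tests therefore show that detection and healing logic is correct under the
stated fault model; they do not predict absolute recovery times on real
infrastructure.

## Progress analytics

Samples are sorted by completion time (ties broken by run id, inherited
from the tracker export, for deterministic binning) and split into
equal-count bins, remainder to the final bin. Bin *b*'s duration is the gap
between its last completion and the previous bin's last completion (bin 1
starts at the analysis start date). Using the analysis start — not the
first completion — charges ramp-up, failed attempts and downtime to the
pipeline, which is the intended semantics of calendar-time effectiveness.

- `r_opt = min_b { duration_b / duration_total / 5 }` over 20 bins of 5%:
  the best demonstrated per-1% pace. `r_opt ≤ 0.01`, with equality iff the
  series is perfectly uniform.
- Effectiveness per 1% bin: `e_i = r_opt / t_i` — a ratio of progress
  *rates* (rates are reciprocals of time fractions, so the actual/target
  rate ratio is the inverted time ratio). Higher is better, 1 is ideal;
  `e_i` may exceed 1 when a 1% bin beats the best 5% bin's pace and is not
  clamped. A zero-duration 1% bin (mass completion tie) is capped at a
  configurable ceiling (default 100) and flagged, rather than propagating
  infinity.
- `μ_e` is the arithmetic mean of `e_i`; expected duration `d = 1/μ_e` in
  multiples of the ideal duration; the direct estimate `1/(100·r_opt)` is
  also reported.
- Uniformity deviation per 1% bin: `|cumulative time % − cumulative
  sample %|`, with mean/min/max/sd across bins.

All statistics depend only on time *fractions*, hence are invariant under
shifting and scaling of timestamps (property-tested). Equal-count binning
makes uniform-series statistics exact only when the sample count is a
multiple of the bin count; generated fixtures use multiples of 100. In
multi-pipeline comparison, pipelines whose completion dates are known
artefacts (e.g. batch uploads) can be excluded from the effectiveness block
while still receiving uniformity statistics.

Rounding is half-up and happens only at the presentation layer
(`overhead_percentage`, report rendering); internal values keep full
precision.

## Acceptance experiment sizes

`scripts/acceptance.py` uses 200-sample generated series for the shape
statistics, a 4×2-core simulated cluster with 40 fixed-duration samples and
15% stuck-task probability for the paired healing experiment, and 8 hosts ×
71 evaluation points for detection accuracy. These sizes were chosen so the
full script runs in seconds while every quantity is still computed, not
asserted; the analytic quantities (duration ratios, site totals, overhead
percentages) are size-independent formula evaluations on their published
inputs.

## Known limitations

- The tracker is single-process; concurrency control and multi-user access
  are out of scope.
- Rule selectors are glob-over-host plus exact metric name; no expression
  grammar.
- The simulator's queue is a single FIFO; no priorities or fairness.
- Effectiveness statistics require ≥ 100 samples (1% bins must be
  non-empty in the equal-count scheme); small cohorts get binning and
  `r_opt` but not `e_i`.
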