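"""Pipeline progress-rate effectiveness and uniformity statistics.

Given a per-sample completion-timestamp series for a pipeline (one cohort
analysis run at constant resource allocation), these statistics summarise
how close the pipeline came to the best sustained pace its infrastructure
demonstrated, and how evenly progress was spread over the analysis window:

* The samples, ordered by completion, are split into 20 equal-count bins
  (5% each).  The **target (optimal) processing rate** is the smallest
  fraction of total analysis time in which any 5% bin was processed,
  rescaled to a per-1% rate::

      r_opt = min_b { duration_b / duration_total / 5 }

* **Effectiveness** of each 1% bin is the ratio of actual to target
  progress rate, e_i = r_opt / t_i, where t_i is the fraction of total
  time spent on bin i (a rate is the reciprocal of a time-per-unit-work, so
  the rate ratio equals the inverted time-fraction ratio).  Its mean μ_e
  summarises the pipeline, and the **expected duration** is d = 1/μ_e in
  multiples of the ideal duration d_opt.

* **Uniformity deviation** is the absolute gap, in percentage points,
  between the cumulative fraction of analysis time spent and the cumulative
  fraction of samples completed, per 1% bin; an ideal execution processes
  1% of samples in 1% of the time and deviates 0 everywhere.

Total analysis time is measured from the analysis start date to the last
completion, so time lost to failed attempts and downtime is included.
Cohort accounting helpers (sites genotyped = sites × samples, management
overhead percentage) round out the reporting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_RATE_BINS = 20  # 5% sample bins for the target-rate estimate
DEFAULT_PERCENT_BINS = 100  # 1% sample bins for effectiveness/uniformity
ZERO_BIN_EFFECTIVENESS_CEILING = 100.0


def _utc(ts: datetime) -> datetime:
    if ts.tzinfo is None:
        return ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


@dataclass(frozen=True)
class CompletionSeries:
    """Per-sample completion timestamps of one pipeline, sorted ascending."""

    pipeline_name: str
    analysis_start: datetime
    completions: tuple[datetime, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "analysis_start", _utc(self.analysis_start))
        object.__setattr__(
            self, "completions", tuple(_utc(c) for c in self.completions)
        )
        if not self.completions:
            raise ValueError("completion series must contain at least one sample")
        if any(b < a for a, b in zip(self.completions, self.completions[1:])):
            raise ValueError("completions must be sorted ascending")
        if self.completions[0] < self.analysis_start:
            raise ValueError("completion precedes analysis start")

    def __len__(self) -> int:
        return len(self.completions)

    def elapsed_seconds(self) -> np.ndarray:
        """Completion offsets from the analysis start, in seconds."""
        start = self.analysis_start
        return np.array(
            [(c - start).total_seconds() for c in self.completions], dtype=float
        )

    @property
    def total_seconds(self) -> float:
        return float((self.completions[-1] - self.analysis_start).total_seconds())


@dataclass(frozen=True)
class ProgressBins:
    """Per-bin fractions of total analysis time; sums to 1."""

    n_bins: int
    bin_time_fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.bin_time_fractions) != self.n_bins:
            raise ValueError("fraction count must equal n_bins")
        if abs(sum(self.bin_time_fractions) - 1.0) > 1e-9:
            raise ValueError("bin time fractions must sum to 1")


@dataclass(frozen=True)
class EffectivenessProfile:
    pipeline_name: str
    r_opt: float
    e_i: tuple[float, ...]
    mean_effectiveness: float
    expected_duration_ratio: float  # 1 / mu_e, multiples of the ideal duration
    direct_duration_ratio: float  # 1 / (100 r_opt)
    capped_bins: tuple[int, ...] = ()  # 1%-bin indices with zero duration


@dataclass(frozen=True)
class UniformityReport:
    pipeline_name: str
    deviations: tuple[float, ...]  # percentage points, one per 1% bin
    mean: float
    min: float
    max: float
    sd: float


@dataclass(frozen=True)
class ResourceReport:
    workflow_cpu_hours: float
    overhead_cpu_hours: float
    overhead_pct: float
    genotyped_site_total: int


# ---------------------------------------------------------------------------
# Binning


def bin_time_fractions(series: CompletionSeries, n_bins: int) -> ProgressBins:
    """Split the series into equal-count completion-order bins.

    Remainder samples go to the final bin.  Bin b's duration is the gap
    between the last completion of bin b and the last completion of bin
    b−1 (bin 1 starts at the analysis start); fractions are durations over
    the total duration (analysis start to last completion).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    n = len(series)
    if n < n_bins:
        raise ValueError(f"series has {n} samples, fewer than {n_bins} bins")
    total = series.total_seconds
    if total <= 0:
        raise ValueError("series spans zero total time")
    elapsed = series.elapsed_seconds()
    per_bin = n // n_bins  # remainder joins the last bin
    boundaries = [elapsed[(b + 1) * per_bin - 1] for b in range(n_bins - 1)]
    boundaries.append(elapsed[-1])
    durations = np.diff([0.0] + boundaries)
    return ProgressBins(n_bins=n_bins, bin_time_fractions=tuple(durations / total))


def optimal_rate(series: CompletionSeries, n_bins: int = DEFAULT_RATE_BINS) -> float:
    """Target processing rate r_opt = min_b duration_b/duration_total/5.

    The smallest share of total analysis time in which any 5% sample bin
    was processed, scaled to a per-1% rate; ≤ 0.01, with equality only for
    a perfectly uniform series.
    """
    bins = bin_time_fractions(series, n_bins)
    pct_per_bin = 100.0 / n_bins
    return min(bins.bin_time_fractions) / pct_per_bin


def effectiveness_profile(
    series: CompletionSeries,
    zero_bin_ceiling: float = ZERO_BIN_EFFECTIVENESS_CEILING,
) -> EffectivenessProfile:
    """Per-1%-bin effectiveness e_i = r_opt / t_i, with μ_e and d = 1/μ_e.

    A 1% bin of zero duration (mass completion tie) would make e_i
    infinite; it is capped at ``zero_bin_ceiling`` and flagged in
    ``capped_bins``.  e_i may exceed 1 when a 1% bin is faster than the
    best 5% bin; no clamp is applied.
    """
    if len(series) < DEFAULT_PERCENT_BINS:
        raise ValueError(
            f"effectiveness requires at least {DEFAULT_PERCENT_BINS} samples"
        )
    r_opt = optimal_rate(series)
    t = np.asarray(
        bin_time_fractions(series, DEFAULT_PERCENT_BINS).bin_time_fractions
    )
    capped = tuple(int(i) for i in np.nonzero(t <= 0.0)[0])
    with np.errstate(divide="ignore"):
        e = np.where(t > 0.0, r_opt / np.where(t > 0.0, t, 1.0), zero_bin_ceiling)
    mu_e = float(e.mean())
    return EffectivenessProfile(
        pipeline_name=series.pipeline_name,
        r_opt=r_opt,
        e_i=tuple(float(x) for x in e),
        mean_effectiveness=mu_e,
        expected_duration_ratio=1.0 / mu_e,
        direct_duration_ratio=1.0 / (DEFAULT_PERCENT_BINS * r_opt),
        capped_bins=capped,
    )


def expected_duration_ratio(mean_effectiveness: float) -> float:
    """Expected analysis duration d = 1/μ_e, in multiples of the ideal."""
    if mean_effectiveness <= 0:
        raise ValueError("mean effectiveness must be positive")
    return 1.0 / mean_effectiveness


def relative_duration_percent(mu_a: float, mu_b: float) -> float:
    """How much longer pipeline set A runs than B: ((1/μ_a)/(1/μ_b) − 1)·100."""
    return (expected_duration_ratio(mu_a) / expected_duration_ratio(mu_b) - 1.0) * 100.0


def uniformity_deviation(series: CompletionSeries) -> UniformityReport:
    """Per-1%-bin |cumulative time % − cumulative sample %| deviations."""
    if len(series) < DEFAULT_PERCENT_BINS:
        raise ValueError(
            f"uniformity requires at least {DEFAULT_PERCENT_BINS} samples"
        )
    t = np.asarray(
        bin_time_fractions(series, DEFAULT_PERCENT_BINS).bin_time_fractions
    )
    y = np.cumsum(t) * 100.0
    x = np.arange(1, DEFAULT_PERCENT_BINS + 1, dtype=float)
    dev = np.abs(y - x)
    return UniformityReport(
        pipeline_name=series.pipeline_name,
        deviations=tuple(float(d) for d in dev),
        mean=float(dev.mean()),
        min=float(dev.min()),
        max=float(dev.max()),
        sd=float(dev.std(ddof=1)),
    )


# ---------------------------------------------------------------------------
# Multi-pipeline comparison


def compare_pipelines(
    series_list: Sequence[CompletionSeries],
    exclusions: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-pipeline effectiveness and uniformity summary table.

    ``exclusions`` (e.g. pipelines whose completion dates are batch-upload
    artefacts rather than real progress) are dropped from the effectiveness
    block but still receive uniformity statistics.  The returned frame
    carries the group mean of μ_e over retained pipelines in
    ``df.attrs["group_mean_effectiveness"]``.
    """
    excluded = set(exclusions)
    retained = [s for s in series_list if s.pipeline_name not in excluded]
    if not retained:
        raise ValueError("all pipelines excluded from effectiveness analysis")
    rows = []
    mu_values = []
    for series in series_list:
        row: dict[str, object] = {"pipeline": series.pipeline_name,
                                  "n_samples": len(series),
                                  "excluded_from_effectiveness":
                                      series.pipeline_name in excluded}
        uni = uniformity_deviation(series)
        row.update(
            uniformity_mean=uni.mean, uniformity_min=uni.min,
            uniformity_max=uni.max, uniformity_sd=uni.sd,
        )
        if series.pipeline_name not in excluded:
            prof = effectiveness_profile(series)
            row.update(
                r_opt=prof.r_opt,
                mean_effectiveness=prof.mean_effectiveness,
                expected_duration_ratio=prof.expected_duration_ratio,
            )
            mu_values.append(prof.mean_effectiveness)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["group_mean_effectiveness"] = float(np.mean(mu_values))
    return df


# ---------------------------------------------------------------------------
# Cohort / overhead accounting


def total_genotyped_sites(n_sites_per_sample: int, n_samples: int) -> int:
    """Joint genotyping evaluates every site in every sample: exact product."""
    if n_sites_per_sample < 0 or n_samples < 0:
        raise ValueError("counts must be non-negative")
    return int(n_sites_per_sample) * int(n_samples)


def overhead_percentage(
    overhead_hours: float, denominator_hours: float, decimals: int = 1
) -> float:
    """Management overhead as a percentage, rounded half-up.

    The caller chooses whether ``denominator_hours`` already includes the
    overhead (conventions differ between reports); values are kept at full
    precision internally and rounded only here, at the presentation layer.
    """
    if denominator_hours <= 0:
        raise ValueError("denominator must be positive")
    if overhead_hours < 0:
        raise ValueError("overhead must be non-negative")
    if overhead_hours > denominator_hours:
        raise ValueError("overhead exceeds denominator")
    pct = Decimal(100) * Decimal(str(overhead_hours)) / Decimal(str(denominator_hours))
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# I/O: the completion-series CSV dialect + analysis-start sidecar


def load_completion_csv(
    csv_path: str | Path, start_sidecar: str | Path | None = None
) -> list[CompletionSeries]:
    """Read ``pipeline,sample_id,completed_at`` CSV into one series per pipeline.

    ``start_sidecar`` is a JSON mapping pipeline → ISO-8601 analysis start;
    pipelines absent from the sidecar use their earliest completion.
    """
    df = pd.read_csv(csv_path)
    required = {"pipeline", "sample_id", "completed_at"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"completion CSV lacks columns: {sorted(missing)}")
    starts: dict[str, datetime] = {}
    if start_sidecar is not None:
        with open(start_sidecar) as fh:
            starts = {
                k: datetime.fromisoformat(v) for k, v in json.load(fh).items()
            }
    out = []
    for name, group in df.groupby("pipeline", sort=True):
        times = sorted(
            datetime.fromisoformat(ts) for ts in group["completed_at"]
        )
        start = starts.get(str(name), times[0])
        out.append(
            CompletionSeries(
                pipeline_name=str(name),
                analysis_start=start,
                completions=tuple(times),
            )
        )
    return out


def summary_report(df: pd.DataFrame) -> str:
    """Plain-text rendering of a :func:`compare_pipelines` table."""
    lines = ["pipeline progress summary", "=" * 25]
    for _, row in df.iterrows():
        lines.append(f"pipeline: {row['pipeline']} (n={row['n_samples']})")
        if row.get("excluded_from_effectiveness"):
            lines.append("  effectiveness: excluded")
        elif not math.isnan(row.get("mean_effectiveness", float("nan"))):
            lines.append(
                f"  r_opt={row['r_opt']:.4f}  mu_e={row['mean_effectiveness']:.3f}"
                f"  expected duration={row['expected_duration_ratio']:.2f}x ideal"
            )
        lines.append(
            f"  uniformity deviation: mean={row['uniformity_mean']:.1f}%"
            f" min={row['uniformity_min']:.1f}% max={row['uniformity_max']:.1f}%"
            f" sd={row['uniformity_sd']:.1f}%"
        )
    mu = df.attrs.get("group_mean_effectiveness")
    if mu is not None:
        lines.append(f"group mean effectiveness: {mu:.3f}")
    return "\n".join(lines) + "\n"
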