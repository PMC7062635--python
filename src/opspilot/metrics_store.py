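"""Time-stamped host health metrics: ingestion, windowed queries, aggregation.

Hosts emit samples such as ``cpu_load``, ``mem_used_fraction`` and the
liveness convention ``heartbeat`` (value 1).  The store keeps every sample
in memory per (host, metric) series, sorted by timestamp, and offers
half-open window queries ``[start, end)`` so adjacent windows partition a
series exactly.  JSONL persistence (one object per line) replaces a
time-series database at desk scale.
"""

from __future__ import annotations

import json
import logging
import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

AGGREGATORS = ("mean", "max", "min", "last", "count")


class EmptyWindow(ValueError):
    """mean/max/min/last requested on a window with no samples."""


def _utc(ts: datetime) -> datetime:
    if ts.tzinfo is None:
        return ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


@dataclass(frozen=True, order=True)
class MetricSample:
    """One (host, metric, time, value) observation."""

    timestamp: datetime
    host_id: str = field(compare=False)
    metric_name: str = field(compare=False)
    value: float = field(compare=False)
    tags: Mapping[str, str] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamp", _utc(self.timestamp))

    def to_json(self) -> str:
        obj = {
            "host": self.host_id,
            "metric": self.metric_name,
            "ts": self.timestamp.isoformat(),
            "value": self.value,
        }
        if self.tags:
            obj["tags"] = dict(self.tags)
        return json.dumps(obj)

    @classmethod
    def from_json(cls, line: str) -> "MetricSample":
        obj = json.loads(line)
        return cls(
            timestamp=datetime.fromisoformat(obj["ts"]),
            host_id=obj["host"],
            metric_name=obj["metric"],
            value=float(obj["value"]),
            tags=obj.get("tags"),
        )


@dataclass
class MetricWindow:
    """Samples of one (host, metric) series in half-open [start, end)."""

    host_id: str
    metric_name: str
    start: datetime
    end: datetime
    samples: list[MetricSample]


def aggregate(window: MetricWindow, aggregator: str) -> float:
    """Standard aggregate over a window; see :data:`AGGREGATORS`.

    ``count`` is defined on an empty window (0); the others raise
    :class:`EmptyWindow`, which absence-detection consumes upstream.
    """
    if aggregator not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    values = [s.value for s in window.samples]
    if aggregator == "count":
        return float(len(values))
    if not values:
        raise EmptyWindow(
            f"no samples for {window.host_id}/{window.metric_name} in "
            f"[{window.start.isoformat()}, {window.end.isoformat()})"
        )
    if aggregator == "mean":
        return sum(values) / len(values)
    if aggregator == "max":
        return max(values)
    if aggregator == "min":
        return min(values)
    return values[-1]  # last


class MetricsStore:
    """Append-only per-(host, metric) series with windowed queries."""

    def __init__(self) -> None:
        self._series: dict[tuple[str, str], list[MetricSample]] = {}
        self.rejected_count = 0

    def ingest(self, sample: MetricSample) -> bool:
        """Append a sample to its series; reject non-finite values.

        Returns True on acceptance.  Out-of-order arrivals are placed by
        timestamp so every series stays sorted.
        """
        if not math.isfinite(sample.value):
            self.rejected_count += 1
            logger.warning(
                "rejected non-finite %s sample from %s",
                sample.metric_name, sample.host_id,
            )
            return False
        insort(self._series.setdefault((sample.host_id, sample.metric_name), []), sample)
        return True

    def ingest_many(self, samples: Iterable[MetricSample]) -> int:
        return sum(self.ingest(s) for s in samples)

    def hosts(self, metric_name: str | None = None) -> list[str]:
        return sorted(
            {h for (h, m) in self._series if metric_name is None or m == metric_name}
        )

    def series(self, host_id: str, metric_name: str) -> list[MetricSample]:
        return list(self._series.get((host_id, metric_name), []))

    def window(
        self, host_id: str, metric_name: str, start: datetime, end: datetime
    ) -> MetricWindow:
        start, end = _utc(start), _utc(end)
        samples = self._series.get((host_id, metric_name), [])
        lo = bisect_left([s.timestamp for s in samples], start)
        hi = bisect_left([s.timestamp for s in samples], end)
        return MetricWindow(host_id, metric_name, start, end, samples[lo:hi])

    def last_timestamp(self, host_id: str, metric_name: str) -> datetime | None:
        samples = self._series.get((host_id, metric_name))
        return samples[-1].timestamp if samples else None

    # -- JSONL persistence --------------------------------------------------

    def dump_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key in sorted(self._series):
                for sample in self._series[key]:
                    fh.write(sample.to_json() + "\n")

    @classmethod
    def load_jsonl(cls, path: str | Path) -> "MetricsStore":
        store = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    store.ingest(MetricSample.from_json(line))
        return store

    def __len__(self) -> int:
        return sum(len(v) for v in self._series.values())

    def iter_samples(self) -> Iterator[MetricSample]:
        for key in sorted(self._series):
            yield from self._series[key]
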