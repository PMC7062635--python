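from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from opspilot.progress_analytics import CompletionSeries
from opspilot.run_tracker import Analysis, Tracker, Workflow

EPOCH = datetime(2026, 1, 1, tzinfo=timezone.utc)


def t(seconds: float) -> datetime:
    return EPOCH + timedelta(seconds=seconds)


def make_series(times, name: str = "p", start: datetime = EPOCH) -> CompletionSeries:
    return CompletionSeries(
        pipeline_name=name,
        analysis_start=start,
        completions=tuple(t(x) for x in times),
    )


@pytest.fixture
def tracker() -> Tracker:
    tr = Tracker()
    tr.register_workflow(Workflow("wf-1", "freebayes", "1.0"))
    tr.create_analysis(Analysis("an-1", "germline", EPOCH))
    return tr
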