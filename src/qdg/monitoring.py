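"""Longitudinal remote-monitoring analytics.

Covers the between-visit questions a movement-disorders provider asks of
home tapping data: did the patient test often enough for the month to
count (the 16-of-30-days reimbursement rule), did they take their
medication when it was prescribed, how do off/on tests compare within a
day, and is the Mobility Score trending over days-to-weeks.  Session
records are stored as JSON lines; the dashboard report is a versioned
JSON document with one panel per view.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .normative import NormativeReference, flag_abnormal
from .trace import TherapyContext

REPORT_SCHEMA_VERSION = 1
DEFAULT_ADHERENCE_WINDOW_MIN = 120.0


@dataclass
class SessionRecord:
    """One completed, scored test."""

    subject_id: str
    test_time: str  # ISO-8601
    hand: str
    therapy_state: str
    metrics: dict  # nested TrialMetrics dict (see metrics_to_dict)
    scores: dict  # ScorePanel dict
    therapy: Optional[dict] = None

    def to_json_line(self) -> str:
        return json.dumps(
            {
                "subject_id": self.subject_id,
                "test_time": self.test_time,
                "hand": self.hand,
                "therapy_state": self.therapy_state,
                "metrics": self.metrics,
                "scores": self.scores,
                "therapy": self.therapy,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json_line(cls, line: str) -> "SessionRecord":
        d = json.loads(line)
        return cls(**d)


def write_session_store(records: Iterable[SessionRecord], path) -> None:
    Path(path).write_text(
        "".join(r.to_json_line() + "\n" for r in records)
    )


def read_session_store(path) -> List[SessionRecord]:
    return [
        SessionRecord.from_json_line(line)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


@dataclass(frozen=True)
class ComplianceSummary:
    window_start: str  # ISO date
    window_end: str  # ISO date, inclusive
    days_tested: int
    possible_days: int
    twice_daily_days: int
    compliance_ratio: float
    meets_16_of_30: bool
    meets_twice_daily_16_of_30: bool


def compliance_summary(
    test_times: Sequence, window: Tuple[str, str]
) -> ComplianceSummary:
    """Testing-day counts over a calendar window (both ends inclusive).

    ``days_tested`` counts distinct calendar days with at least one
    test; the twice-daily variant needs at least two tests on a day.
    The 16-of-30 criterion is met with 16 or more testing days, the bar
    CMS sets for remote-monitoring reimbursement over a 30-day month.
    """
    start = pd.Timestamp(window[0]).normalize()
    end = pd.Timestamp(window[1]).normalize()
    if end < start:
        raise ValueError(f"empty window {window}")
    possible = int((end - start).days) + 1
    times = pd.to_datetime(list(test_times))
    days = times.normalize()
    in_window = days[(days >= start) & (days <= end)]
    counts = pd.Series(in_window).value_counts()
    days_tested = int(len(counts))
    twice = int((counts >= 2).sum())
    return ComplianceSummary(
        window_start=str(start.date()),
        window_end=str(end.date()),
        days_tested=days_tested,
        possible_days=possible,
        twice_daily_days=twice,
        compliance_ratio=days_tested / possible,
        meets_16_of_30=days_tested >= 16,
        meets_twice_daily_16_of_30=twice >= 16,
    )


def cohort_compliance(
    summaries: Sequence[ComplianceSummary], twice_daily: bool = False
) -> float:
    """Fraction of subjects meeting the 16-of-30-day criterion."""
    if not summaries:
        raise ValueError("no subjects")
    if twice_daily:
        met = sum(s.meets_twice_daily_16_of_30 for s in summaries)
    else:
        met = sum(s.meets_16_of_30 for s in summaries)
    return met / len(summaries)


@dataclass(frozen=True)
class DoseMatch:
    prescribed_time: str
    drug: str
    taken_time: Optional[str]
    delta_minutes: Optional[float]
    missed: bool


def adherence_summary(
    context: TherapyContext,
    day: str,
    window_minutes: float = DEFAULT_ADHERENCE_WINDOW_MIN,
) -> List[DoseMatch]:
    """Match taken doses to the day's prescribed schedule.

    Greedy nearest-in-time matching within ``window_minutes``; each
    taken dose is used at most once; unmatched prescribed doses are
    flagged missed.
    """
    day_ts = pd.Timestamp(day).normalize()
    prescribed = [
        (pd.Timestamp(ts), drug)
        for ts, drug in context.prescribed_doses
        if pd.Timestamp(ts).normalize() == day_ts
    ]
    taken = [
        pd.Timestamp(ts)
        for ts, _ in context.taken_doses
        if pd.Timestamp(ts).normalize() == day_ts
    ]
    # consider candidate pairs in order of increasing |delta|
    pairs = sorted(
        (
            (abs((tk - rx).total_seconds()) / 60.0, i, j)
            for i, (rx, _) in enumerate(prescribed)
            for j, tk in enumerate(taken)
        ),
    )
    rx_match: Dict[int, int] = {}
    used_taken = set()
    for delta, i, j in pairs:
        if delta > window_minutes:
            break
        if i in rx_match or j in used_taken:
            continue
        rx_match[i] = j
        used_taken.add(j)
    out = []
    for i, (rx, drug) in enumerate(prescribed):
        if i in rx_match:
            tk = taken[rx_match[i]]
            out.append(
                DoseMatch(
                    prescribed_time=rx.isoformat(),
                    drug=drug,
                    taken_time=tk.isoformat(),
                    delta_minutes=(tk - rx).total_seconds() / 60.0,
                    missed=False,
                )
            )
        else:
            out.append(
                DoseMatch(
                    prescribed_time=rx.isoformat(),
                    drug=drug,
                    taken_time=None,
                    delta_minutes=None,
                    missed=True,
                )
            )
    return out


@dataclass(frozen=True)
class TrendResult:
    slope: float  # score units per day
    ci95: Tuple[float, float]
    p_value: float
    intercept: float
    n_days: int


def trend_slope(
    days: Sequence[float], scores: Sequence[float]
) -> TrendResult:
    """OLS daily trend of a score series with 95% CI and two-sided p."""
    days = np.asarray(days, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(days) < 3:
        raise ValueError("trend needs at least 3 days")
    X = sm.add_constant(days)
    fit = sm.OLS(scores, X).fit()
    lo, hi = fit.conf_int(alpha=0.05)[1]
    return TrendResult(
        slope=float(fit.params[1]),
        ci95=(float(lo), float(hi)),
        p_value=float(fit.pvalues[1]),
        intercept=float(fit.params[0]),
        n_days=len(days),
    )


def render_report(
    records: Sequence[SessionRecord],
    reference: NormativeReference,
    compliance: Optional[ComplianceSummary] = None,
) -> dict:
    """Dashboard-style JSON with single-test, daily and monthly panels.

    Every metric tile carries its value and normal/abnormal flag (the
    dashboard's green/red colouring); medication markers keep the
    prescribed-vs-taken distinction.
    """
    records = sorted(records, key=lambda r: r.test_time)
    single = None
    if records:
        last = records[-1]
        tiles = {}
        for metric, value in last.metrics["hand"].items():
            tile = {"value": value}
            if metric in reference.metrics and np.isfinite(value):
                tile["flag"] = flag_abnormal(value, reference, metric)
            tiles[metric] = tile
        for metric in ("taps_per_minute", "rest_tremor_pct"):
            tile = {"value": last.metrics[metric]}
            if metric in reference.metrics:
                tile["flag"] = flag_abnormal(
                    last.metrics[metric], reference, metric
                )
            tiles[metric] = tile
        single = {
            "test_time": last.test_time,
            "hand": last.hand,
            "therapy_state": last.therapy_state,
            "metric_tiles": tiles,
            "mobility_score": last.scores["mobility_score"],
            "tremor_severity": last.scores["tremor_severity"],
            "therapy": last.therapy,
        }
    series = {
        "test_time": [r.test_time for r in records],
        "hand": [r.hand for r in records],
        "therapy_state": [r.therapy_state for r in records],
        "mobility_score": [r.scores["mobility_score"] for r in records],
        "tremor_severity": [r.scores["tremor_severity"] for r in records],
    }
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "single_test_panel": single,
        "daily_panel": series,
        "monthly_panel": {
            "n_tests": len(records),
            "compliance": compliance.__dict__ if compliance else None,
        },
    }
    return report
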