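"""The eight per-finger trial metrics and their hand-level aggregation.

Metrics per finger, averaged over the trial's (by default voluntary,
i.e. non-tremor) strikes:

1. press amplitude (mm)                 — bradykinesia: movement size
2. press amplitude CV (SD/mean)         — sequence effect / decrement
3. inter-strike interval, ISI (s)       — cycle period
4. ISI CV                               — arrhythmicity
5. release slope (mm/s)                 — rigidity proxy (lever return)
6. press speed (mm/s)                   — bradykinesia: movement speed
7. dwell time (s)                       — hold at the bottom of a press
8. rest tremor % of trace               — tremor-labelled strike coverage

plus taps per minute (both fingers combined).  Each per-finger value is
the unweighted mean over that finger's strikes; the hand value is the
unweighted mean of the two fingers.  CVs use the sample (n-1) standard
deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .segmentation import SegmentationResult, StrikeEvent, cycle_isis
from .trace import RaftTrace

#: metric keys produced per finger and per hand
METRIC_KEYS = (
    "press_amplitude",
    "press_amplitude_cv",
    "isi",
    "isi_cv",
    "release_slope",
    "press_speed",
    "dwell_time",
)


@dataclass
class TrialMetrics:
    """Per-finger and hand-aggregate metrics for one trial."""

    per_finger: Dict[str, Dict[str, float]]
    hand: Dict[str, float]
    rest_tremor_pct: float
    taps_per_minute: float
    missing_fingers: List[str] = field(default_factory=list)

    @property
    def arrhythmicity_pct(self) -> float:
        return 100.0 * self.hand["isi_cv"]


def _cv(values: np.ndarray) -> float:
    if len(values) < 2:
        return float("nan")
    m = values.mean()
    if m == 0:
        return float("nan")
    return float(values.std(ddof=1) / m)


def _finger_metrics(strikes: List[StrikeEvent]) -> Optional[Dict[str, float]]:
    if not strikes:
        return None
    amps = np.array([s.press_amplitude for s in strikes])
    isis = cycle_isis(strikes)
    return {
        "press_amplitude": float(amps.mean()),
        "press_amplitude_cv": _cv(amps),
        "isi": float(isis.mean()) if len(isis) else float("nan"),
        "isi_cv": _cv(isis),
        "release_slope": float(
            np.mean([s.release_slope for s in strikes])
        ),
        "press_speed": float(np.mean([s.press_speed for s in strikes])),
        "dwell_time": float(np.mean([s.dwell_time for s in strikes])),
    }


def tremor_coverage_pct(
    strikes: List[StrikeEvent], duration: float
) -> float:
    """Percent of the trace covered by tremor-labelled strikes.

    Uses the union of onset->release-end intervals across fingers so
    simultaneous bilateral tremor cannot exceed 100%.
    """
    spans = sorted(
        (s.onset_t, s.end_t) for s in strikes if s.tremor
    )
    covered = 0.0
    cur_start = cur_end = None
    for a, b in spans:
        if cur_end is None or a > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = a, b
        else:
            cur_end = max(cur_end, b)
    if cur_end is not None:
        covered += cur_end - cur_start
    return min(100.0, 100.0 * covered / duration)


def compute_metrics(
    segmentation: SegmentationResult,
    trace: RaftTrace,
    voluntary_only: bool = True,
) -> TrialMetrics:
    """Compute the trial metrics from segmented (and tremor-labelled) strikes.

    When ``voluntary_only`` (the default, matching how the scores are
    built), means and CVs are taken over non-tremor strikes only;
    ``rest_tremor_pct`` always comes from the tremor labels.  A finger
    with zero usable strikes is marked missing and the hand aggregate
    falls back to the other finger.
    """
    all_strikes = segmentation.all_strikes()
    per_finger: Dict[str, Dict[str, float]] = {}
    missing: List[str] = []
    n_voluntary = 0
    for finger, strikes in segmentation.strikes.items():
        use = [s for s in strikes if not (voluntary_only and s.tremor)]
        n_voluntary += len(use)
        fm = _finger_metrics(use)
        if fm is None:
            missing.append(finger)
        else:
            per_finger[finger] = fm
    hand = aggregate_hand(per_finger)
    return TrialMetrics(
        per_finger=per_finger,
        hand=hand,
        rest_tremor_pct=tremor_coverage_pct(all_strikes, trace.duration),
        taps_per_minute=60.0 * n_voluntary / trace.duration,
        missing_fingers=missing,
    )


def aggregate_hand(
    per_finger: Dict[str, Dict[str, float]]
) -> Dict[str, float]:
    """Unweighted mean of the two finger rows; pass-through if one missing."""
    if not per_finger:
        return {k: float("nan") for k in METRIC_KEYS}
    out = {}
    for k in METRIC_KEYS:
        vals = [
            fm[k]
            for fm in per_finger.values()
            if not math.isnan(fm.get(k, float("nan")))
        ]
        out[k] = float(np.mean(vals)) if vals else float("nan")
    return out


def metrics_to_dict(m: TrialMetrics) -> dict:
    """Nested dict mirroring the dashboard panel; JSON-serialisable."""
    return {
        "hand": dict(m.hand),
        "per_finger": {f: dict(v) for f, v in m.per_finger.items()},
        "rest_tremor_pct": m.rest_tremor_pct,
        "taps_per_minute": m.taps_per_minute,
        "arrhythmicity_pct": m.arrhythmicity_pct,
        "missing_fingers": list(m.missing_fingers),
    }
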