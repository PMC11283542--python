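"""Segmentation of lever displacement into press/dwell/release strike cycles.

Each finger's channel is scanned by a four-state hysteresis machine:

* IDLE -> PRESS on an upward crossing of the onset threshold;
* PRESS -> DWELL when the signal stops pushing the running peak upward
  while staying within the dwell band of it;
* DWELL -> RELEASE when the signal leaves the band downward;
* RELEASE -> IDLE when it falls back below half the onset threshold
  (the lower leg of a Schmitt trigger: with a single shared threshold,
  sensor noise straddling it would split one release into several
  spurious strikes).

The strike onset is back-projected from the threshold crossing to the
start of the monotone rise (the last local minimum), so press duration
and press speed refer to the full excursion rather than the
above-threshold part.  Strikes whose peak falls below
``min_strike_amplitude`` are diverted to a debug list instead of being
reported — they are sensor noise or incidental lever contact, not taps.
Alternation between fingers is never enforced; patients violate it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .trace import RaftTrace


@dataclass
class StrikeEvent:
    """One press/dwell/release cycle of a single finger."""

    finger: str  # "index" | "middle"
    channel: str  # "a" | "b"
    onset_t: float  # s, start of the rise
    peak_t: float  # s, time of maximum depression
    press_amplitude: float  # mm, peak depression
    press_duration: float  # s, onset -> first dwell sample
    dwell_time: float  # s
    release_duration: float  # s
    release_amplitude: float  # mm, peak - depression at release end
    end_t: float = 0.0  # s, RELEASE->IDLE crossing
    isi: Optional[float] = None  # s to previous onset, same finger
    tremor: bool = False  # set by the tremor module

    def __post_init__(self):
        if not self.press_amplitude > 0:
            raise ValueError("press_amplitude must be positive")
        for name in ("press_duration", "dwell_time", "release_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def press_speed(self) -> float:
        """mm/s; amplitude over press duration."""
        return self.press_amplitude / self.press_duration

    @property
    def release_slope(self) -> float:
        """mm/s; release amplitude over release duration."""
        return self.release_amplitude / self.release_duration


@dataclass(frozen=True)
class SegmentationParams:
    onset_threshold: float = 0.05  # fraction of device max
    dwell_epsilon_frac: float = 0.02  # band around peak, fraction of max
    min_strike_amplitude: float = 0.5  # mm
    device_max_amplitude: float = 10.0  # mm

    def __post_init__(self):
        if not 0 < self.onset_threshold < 0.5:
            raise ValueError("onset_threshold must lie in (0, 0.5)")
        if self.dwell_epsilon_frac <= 0:
            raise ValueError("dwell_epsilon_frac must be positive")
        if self.min_strike_amplitude < 0:
            raise ValueError("min_strike_amplitude must be non-negative")

    @property
    def onset_mm(self) -> float:
        return self.onset_threshold * self.device_max_amplitude

    @property
    def dwell_epsilon_mm(self) -> float:
        return self.dwell_epsilon_frac * self.device_max_amplitude


@dataclass
class SegmentationResult:
    """Per-finger strikes plus diagnostics."""

    strikes: Dict[str, List[StrikeEvent]]
    discarded: Dict[str, List[StrikeEvent]] = field(default_factory=dict)
    alternation_violations: int = 0

    def all_strikes(self) -> List[StrikeEvent]:
        out = [s for seq in self.strikes.values() for s in seq]
        return sorted(out, key=lambda s: s.onset_t)


_IDLE, _PRESS, _DWELL, _RELEASE = 0, 1, 2, 3


def _segment_channel(
    t: np.ndarray, x: np.ndarray, finger: str, channel: str,
    params: SegmentationParams,
) -> List[StrikeEvent]:
    thr = params.onset_mm
    exit_thr = thr / 2.0  # hysteresis: leave a strike well below entry
    eps = params.dwell_epsilon_mm
    strikes: List[StrikeEvent] = []
    state = _IDLE
    onset_i = peak_i = dwell_i = rel_i = 0
    peak = 0.0
    for i in range(1, len(x)):
        xi = x[i]
        if state == _IDLE:
            if xi > thr and x[i - 1] <= thr:
                # back-project onset to the start of the monotone rise
                j = i - 1
                while j > 0 and x[j - 1] < x[j]:
                    j -= 1
                onset_i = j
                peak_i = i
                peak = xi
                state = _PRESS
        elif state == _PRESS:
            if xi > peak:
                peak = xi
                peak_i = i
            elif xi >= peak - eps:
                dwell_i = i
                state = _DWELL
            else:
                # sharp peak: no resolvable dwell plateau
                dwell_i = i
                state = _RELEASE
                rel_i = i
                if xi < exit_thr:
                    strikes.append(
                        _finish(t, x, finger, channel, onset_i, peak_i, peak,
                                dwell_i, rel_i, i)
                    )
                    state = _IDLE
        elif state == _DWELL:
            if xi < peak - eps:
                rel_i = i
                state = _RELEASE
                if xi < exit_thr:
                    strikes.append(
                        _finish(t, x, finger, channel, onset_i, peak_i, peak,
                                dwell_i, rel_i, i)
                    )
                    state = _IDLE
            elif xi > peak:
                # noise ripple on the plateau: track the peak but keep
                # the dwell start where the rise first flattened
                peak = xi
                peak_i = i
        elif state == _RELEASE:
            if xi < exit_thr:
                strikes.append(
                    _finish(t, x, finger, channel, onset_i, peak_i, peak,
                            dwell_i, rel_i, i)
                )
                state = _IDLE
    # a cycle truncated by the end of the recording is dropped: its
    # release kinematics are undefined
    return strikes


def _finish(t, x, finger, channel, onset_i, peak_i, peak, dwell_i, rel_i,
            end_i) -> StrikeEvent:
    dt = t[1] - t[0]
    press_dur = max(t[dwell_i] - t[onset_i], dt)
    dwell = max(t[rel_i] - t[dwell_i], 0.0)
    rel_dur = max(t[end_i] - t[rel_i], dt)
    return StrikeEvent(
        finger=finger,
        channel=channel,
        onset_t=float(t[onset_i]),
        peak_t=float(t[peak_i]),
        press_amplitude=float(peak),
        press_duration=float(press_dur),
        dwell_time=float(dwell),
        release_duration=float(rel_dur),
        release_amplitude=float(peak - x[end_i]),
        end_t=float(t[end_i]),
    )


def segment_strikes(
    trace: RaftTrace, params: SegmentationParams | None = None
) -> SegmentationResult:
    """Segment both channels of a trace into strike cycles.

    Returns a :class:`SegmentationResult` keyed by finger name.  A flat
    or empty channel yields an empty strike list, not an error.  Strikes
    below ``min_strike_amplitude`` land in ``result.discarded``.
    """
    if params is None:
        params = SegmentationParams(device_max_amplitude=trace.device_max)
    strikes: Dict[str, List[StrikeEvent]] = {}
    discarded: Dict[str, List[StrikeEvent]] = {}
    for ch in ("a", "b"):
        finger = trace.finger_map[ch]
        raw = _segment_channel(
            trace.timestamps, trace.channel(ch), finger, ch, params
        )
        keep = [s for s in raw if s.press_amplitude >= params.min_strike_amplitude]
        discarded[finger] = [
            s for s in raw if s.press_amplitude < params.min_strike_amplitude
        ]
        prev_onset = None
        for s in keep:
            if prev_onset is not None:
                s.isi = s.onset_t - prev_onset
            prev_onset = s.onset_t
        strikes[finger] = keep
    violations = _count_alternation_violations(strikes)
    return SegmentationResult(
        strikes=strikes, discarded=discarded,
        alternation_violations=violations,
    )


def _count_alternation_violations(strikes: Dict[str, List[StrikeEvent]]) -> int:
    ordered = sorted(
        (s for seq in strikes.values() for s in seq), key=lambda s: s.onset_t
    )
    return sum(
        1
        for prev, cur in zip(ordered, ordered[1:])
        if prev.finger == cur.finger
    )


def cycle_isis(strikes: List[StrikeEvent]) -> np.ndarray:
    """Onset-to-onset inter-strike intervals for one finger's strikes.

    One full press/release cycle per interval; fewer than two strikes
    yields an empty array.
    """
    if len(strikes) < 2:
        return np.array([])
    onsets = np.array([s.onset_t for s in strikes])
    return np.diff(onsets)


def strikes_to_frame(result: SegmentationResult) -> pd.DataFrame:
    """Flatten a segmentation result to one row per strike.

    Column order is part of the strike-table export contract.
    """
    rows = []
    for s in result.all_strikes():
        rows.append(
            {
                "finger": s.finger,
                "channel": s.channel,
                "onset_t": s.onset_t,
                "peak_t": s.peak_t,
                "end_t": s.end_t,
                "press_amplitude": s.press_amplitude,
                "press_duration": s.press_duration,
                "dwell_time": s.dwell_time,
                "release_duration": s.release_duration,
                "release_amplitude": s.release_amplitude,
                "press_speed": s.press_speed,
                "release_slope": s.release_slope,
                "isi": s.isi if s.isi is not None else np.nan,
                "tremor": s.tremor,
            }
        )
    cols = [
        "finger", "channel", "onset_t", "peak_t", "end_t",
        "press_amplitude", "press_duration", "dwell_time",
        "release_duration", "release_amplitude", "press_speed",
        "release_slope", "isi", "tremor",
    ]
    return pd.DataFrame(rows, columns=cols)
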