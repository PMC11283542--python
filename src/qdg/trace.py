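"""Two-lever displacement trace model, on-disk dialect, and pre-analysis QC.

A Quantitative DigitoGraphy (QDG) trial records 30 s of repetitive
alternating finger tapping (RAFT) on two adjacent tensioned levers.  Each
channel is the depression depth of one lever in millimetres, sampled on a
uniform grid at a nominal 200.96 Hz.  The displacement convention is
0 mm = lever fully up, positive = depression depth.

The file dialect is a CSV with columns ``t_s, lever_a_mm, lever_b_mm``
plus a JSON sidecar (``<path>.json``) holding device metadata, subject
metadata and the therapy context.  CSV numbers are written with six
decimal places, so a write/read round trip is numerically exact at that
precision and repeated writes are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

NOMINAL_SAMPLE_RATE = 200.96  # Hz
NOMINAL_DURATION = 30.0  # s
DEVICE_MAX_AMPLITUDE = 10.0  # mm, full lever travel

_THERAPY_STATES = frozenset({"off", "on", "untreated"})


class TraceValidationError(ValueError):
    """A trace or its metadata violates a structural invariant."""


class TraceParseError(ValueError):
    """A trace file does not conform to the documented dialect."""


@dataclass(frozen=True)
class RaftTrace:
    """One two-channel RAFT displacement recording.

    Attributes
    ----------
    sample_rate : float
        Samples per second (nominal 200.96 Hz).
    timestamps : np.ndarray
        Seconds from trial start; strictly increasing uniform grid.
    channel_a, channel_b : np.ndarray
        Lever depression depth in mm, same length as ``timestamps``.
    finger_map : dict
        Maps ``"a"``/``"b"`` to ``"index"``/``"middle"``.
    hand : str
        ``"L"`` or ``"R"``.
    duration : float
        Trial duration in seconds (nominal 30).
    device_max : float
        Maximum lever travel in mm.
    """

    sample_rate: float
    timestamps: np.ndarray
    channel_a: np.ndarray
    channel_b: np.ndarray
    finger_map: dict = field(
        default_factory=lambda: {"a": "index", "b": "middle"}
    )
    hand: str = "R"
    duration: float = NOMINAL_DURATION
    device_max: float = DEVICE_MAX_AMPLITUDE

    def __post_init__(self):
        for name in ("timestamps", "channel_a", "channel_b"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        validate_trace(self)

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    def channel(self, key: str) -> np.ndarray:
        return {"a": self.channel_a, "b": self.channel_b}[key]

    def swap_channels(self) -> "RaftTrace":
        """Relabel the levers (a<->b); used for symmetry checks."""
        return replace(
            self,
            channel_a=self.channel_b,
            channel_b=self.channel_a,
            finger_map={"a": self.finger_map["b"], "b": self.finger_map["a"]},
        )


@dataclass(frozen=True)
class TrialMetadata:
    subject_id: str
    age: float
    test_time: str = ""  # ISO-8601
    therapy_state: str = "untreated"
    more_affected_side: str = "unknown"  # L | R | unknown

    def __post_init__(self):
        if not self.age > 0:
            raise TraceValidationError(f"age must be positive, got {self.age}")
        if self.therapy_state not in _THERAPY_STATES:
            raise TraceValidationError(
                f"therapy_state must be one of {sorted(_THERAPY_STATES)}, "
                f"got {self.therapy_state!r}"
            )
        if self.more_affected_side not in ("L", "R", "unknown"):
            raise TraceValidationError(
                f"more_affected_side must be L, R or unknown, "
                f"got {self.more_affected_side!r}"
            )


@dataclass(frozen=True)
class TherapyContext:
    """Prescribed vs actually-taken doses and optional DBS settings.

    Doses are ``(iso_timestamp, drug_label)`` pairs; both lists may be
    empty (e.g. an untreated subject).
    """

    prescribed_doses: tuple = ()
    taken_doses: tuple = ()
    dbs_settings: Optional[dict] = None

    def __post_init__(self):
        for doses in (self.prescribed_doses, self.taken_doses):
            for ts, _label in doses:
                pd.Timestamp(ts)  # raises on invalid timestamp
        object.__setattr__(
            self, "prescribed_doses", tuple(map(tuple, self.prescribed_doses))
        )
        object.__setattr__(
            self, "taken_doses", tuple(map(tuple, self.taken_doses))
        )


@dataclass(frozen=True)
class QCReport:
    delayed_start: bool
    single_key: bool
    notes: str = ""

    @property
    def passed(self) -> bool:
        return not (self.delayed_start or self.single_key)


def validate_trace(trace: RaftTrace) -> None:
    """Enforce every structural invariant; raise TraceValidationError."""
    t = trace.timestamps
    if len(trace.channel_a) != len(t) or len(trace.channel_b) != len(t):
        raise TraceValidationError(
            "channel lengths differ from timestamp length: "
            f"t={len(t)}, a={len(trace.channel_a)}, b={len(trace.channel_b)}"
        )
    if len(t) < 2:
        raise TraceValidationError("trace must contain at least 2 samples")
    dt = np.diff(t)
    if not np.all(dt > 0):
        raise TraceValidationError("timestamps must be strictly increasing")
    period = 1.0 / trace.sample_rate
    if np.any(np.abs(dt - period) > period):
        raise TraceValidationError(
            "timestamps deviate from the uniform grid by more than one "
            "sample period"
        )
    for name in ("channel_a", "channel_b"):
        ch = getattr(trace, name)
        if np.any(ch < 0):
            raise TraceValidationError(f"{name} has negative displacement")
        if np.any(ch > trace.device_max):
            raise TraceValidationError(
                f"{name} exceeds device maximum {trace.device_max} mm"
            )
    expected = trace.duration * trace.sample_rate
    if abs(len(t) - expected) > 0.01 * expected:
        raise TraceValidationError(
            f"sample count {len(t)} not within 1% of "
            f"duration x rate = {expected:.1f}"
        )
    if trace.hand not in ("L", "R"):
        raise TraceValidationError(f"hand must be L or R, got {trace.hand!r}")
    if set(trace.finger_map) != {"a", "b"} or set(
        trace.finger_map.values()
    ) != {"index", "middle"}:
        raise TraceValidationError(
            "finger_map must map channels a/b onto index/middle"
        )


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_trace(
    trace: RaftTrace,
    meta: TrialMetadata,
    path,
    therapy: Optional[TherapyContext] = None,
) -> None:
    """Write a trace as CSV plus JSON sidecar.

    Validation runs before any file is touched, so a trace violating its
    invariants never produces a partial file.  Numbers are formatted with
    six decimal places; two writes of the same trace are byte-identical.
    """
    validate_trace(trace)
    path = Path(path)
    df = pd.DataFrame(
        {
            "t_s": trace.timestamps,
            "lever_a_mm": trace.channel_a,
            "lever_b_mm": trace.channel_b,
        }
    )
    sidecar = {
        "schema_version": 1,
        "sample_rate_hz": trace.sample_rate,
        "duration_s": trace.duration,
        "device_max_mm": trace.device_max,
        "hand": trace.hand,
        "finger_map": trace.finger_map,
        "subject": {
            "subject_id": meta.subject_id,
            "age_years": meta.age,
            "test_time": meta.test_time,
            "therapy_state": meta.therapy_state,
            "more_affected_side": meta.more_affected_side,
        },
        "therapy": {
            "prescribed_doses": list(map(list, therapy.prescribed_doses))
            if therapy
            else [],
            "taken_doses": list(map(list, therapy.taken_doses))
            if therapy
            else [],
            "dbs_settings": therapy.dbs_settings if therapy else None,
        },
    }
    df.to_csv(path, index=False, float_format="%.6f")
    _sidecar_path(path).write_text(
        json.dumps(sidecar, indent=1, sort_keys=True) + "\n"
    )


def read_trace(path):
    """Read a trace written by :func:`write_trace`.

    Returns ``(RaftTrace, TrialMetadata, TherapyContext)``.  Malformed
    headers raise :class:`TraceParseError` naming the offending field;
    invariant violations raise :class:`TraceValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = ["t_s", "lever_a_mm", "lever_b_mm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceParseError(
            f"trace CSV {path} missing required column(s): {missing}"
        )
    side = _sidecar_path(path)
    if not side.exists():
        raise TraceParseError(f"missing JSON sidecar {side}")
    try:
        sc = json.loads(side.read_text())
    except json.JSONDecodeError as e:
        raise TraceParseError(f"sidecar {side} is not valid JSON: {e}") from e
    for key in ("sample_rate_hz", "duration_s", "hand", "subject"):
        if key not in sc:
            raise TraceParseError(f"sidecar missing field {key!r}")
    trace = RaftTrace(
        sample_rate=float(sc["sample_rate_hz"]),
        timestamps=df["t_s"].to_numpy(),
        channel_a=df["lever_a_mm"].to_numpy(),
        channel_b=df["lever_b_mm"].to_numpy(),
        finger_map=sc.get("finger_map", {"a": "index", "b": "middle"}),
        hand=sc["hand"],
        duration=float(sc["duration_s"]),
        device_max=float(sc.get("device_max_mm", DEVICE_MAX_AMPLITUDE)),
    )
    subj = sc["subject"]
    meta = TrialMetadata(
        subject_id=subj["subject_id"],
        age=float(subj["age_years"]),
        test_time=subj.get("test_time", ""),
        therapy_state=subj.get("therapy_state", "untreated"),
        more_affected_side=subj.get("more_affected_side", "unknown"),
    )
    th = sc.get("therapy", {})
    therapy = TherapyContext(
        prescribed_doses=tuple(map(tuple, th.get("prescribed_doses", []))),
        taken_doses=tuple(map(tuple, th.get("taken_doses", []))),
        dbs_settings=th.get("dbs_settings"),
    )
    return trace, meta, therapy


def qc_screen(
    trace: RaftTrace, window: float = 5.0, activity_threshold: float = 1.0
) -> QCReport:
    """Screen a trace for the two remote-use error modes.

    ``delayed_start`` is flagged when neither lever is depressed beyond
    ``activity_threshold`` (mm) within the first ``window`` seconds;
    ``single_key`` when exactly one lever is.  Both mirror the in-app
    prompt that asks the user to redo the task.
    """
    if window > trace.duration:
        raise ValueError(
            f"QC window {window} s exceeds trace duration {trace.duration} s"
        )
    mask = trace.timestamps < window
    a_active = bool(np.any(trace.channel_a[mask] > activity_threshold))
    b_active = bool(np.any(trace.channel_b[mask] > activity_threshold))
    delayed = not (a_active or b_active)
    single = a_active != b_active
    notes = []
    if delayed:
        notes.append(f"no key pressed beyond {activity_threshold} mm "
                     f"within first {window} s")
    if single:
        which = "a" if a_active else "b"
        notes.append(f"only channel {which} active within first {window} s")
    return QCReport(
        delayed_start=delayed, single_key=single, notes="; ".join(notes)
    )
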