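"""Synthetic two-lever RAFT trace generator with ground-truth labels.

The simulator emulates the 30-second repetitive alternating finger
tapping task: each finger presses its lever at the configured tap rate,
half a cycle out of phase with the other finger.  A strike is a
cosine-ramp press, a flat dwell and a cosine-ramp release, returning to
the raised-lever baseline (0 mm).  Configurable pathology:

* press depth mean/SD (healthy full press 8.67 +/- 0.12 mm);
* exponential per-strike amplitude decay (the sequence effect);
* inter-strike-interval jitter (arrhythmicity);
* tremor bursts: contiguous windows covering a configurable fraction of
  the timeline in which voluntary taps are replaced by low-amplitude
  oscillatory strikes at a 3-8 Hz tremor rate, on both levers;
* additive Gaussian sensor noise, clipped to the physical range.

Every emitted strike carries a ground-truth record (finger, onset,
amplitude, phase durations, tremor flag), which the segmentation and
classification modules treat as the oracle.  Everything is deterministic
given the profile seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .trace import RaftTrace

HEALTHY_PRESS_DEPTH_MEAN = 8.67  # mm, healthy-control full press
HEALTHY_PRESS_DEPTH_SD = 0.12  # mm
HEALTHY_TAP_RATE = 2.5  # cycles/s per finger


@dataclass(frozen=True)
class SimulationProfile:
    """All knobs of one simulated trial."""

    sample_rate: float = 200.96  # Hz
    duration: float = 30.0  # s
    tap_rate: float = HEALTHY_TAP_RATE  # cycles/s per finger
    press_depth_mean: float = HEALTHY_PRESS_DEPTH_MEAN  # mm
    press_depth_sd: float = HEALTHY_PRESS_DEPTH_SD  # mm
    depth_decay_rate: float = 0.0  # per-strike exponential decay
    isi_jitter_cv: float = 0.0
    press_duration: float = 0.10  # s
    release_duration: float = 0.10  # s
    dwell_time: float = 0.06  # s
    phase_jitter_cv: float = 0.0  # jitter on the three phase durations
    tremor_fraction: float = 0.0  # fraction of timeline in tremor bursts
    tremor_rate: float = 5.0  # Hz, strike rate inside bursts
    tremor_amplitude_mean: float = 1.5  # mm
    tremor_amplitude_sd: float = 0.2  # mm
    noise_sd: float = 0.0  # mm additive sensor noise
    device_max: float = 10.0  # mm
    hand: str = "R"
    seed: int = 0

    def __post_init__(self):
        for name in ("sample_rate", "duration", "tap_rate", "tremor_rate",
                     "press_duration", "release_duration", "dwell_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.tremor_fraction <= 1.0:
            raise ValueError("tremor_fraction must lie in [0, 1]")
        if self.depth_decay_rate < 0:
            raise ValueError("depth_decay_rate must be non-negative")
        span = self.press_duration + self.dwell_time + self.release_duration
        if span >= 1.0 / self.tap_rate:
            raise ValueError(
                f"strike span {span:.3f} s does not fit in the "
                f"{1.0 / self.tap_rate:.3f} s tap period"
            )


@dataclass
class GroundTruthStrike:
    finger: str
    channel: str
    onset: float  # s
    amplitude: float  # mm
    press_duration: float  # s
    dwell_time: float  # s
    release_duration: float  # s
    tremor: bool

    @property
    def span(self) -> float:
        return self.press_duration + self.dwell_time + self.release_duration


@dataclass
class GroundTruth:
    strikes: List[GroundTruthStrike]
    tremor_windows: List[Tuple[float, float]] = field(default_factory=list)

    def per_finger(self) -> Dict[str, List[GroundTruthStrike]]:
        out: Dict[str, List[GroundTruthStrike]] = {}
        for s in sorted(self.strikes, key=lambda s: s.onset):
            out.setdefault(s.finger, []).append(s)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "finger": s.finger,
                    "channel": s.channel,
                    "onset": s.onset,
                    "amplitude": s.amplitude,
                    "press_duration": s.press_duration,
                    "dwell_time": s.dwell_time,
                    "release_duration": s.release_duration,
                    "tremor": s.tremor,
                }
                for s in sorted(self.strikes, key=lambda s: s.onset)
            ]
        )


def _strike_waveform(
    t: np.ndarray, onset: float, amp: float, press: float, dwell: float,
    release: float,
) -> np.ndarray:
    """Cosine-ramp press, flat dwell, cosine-ramp release at the grid ``t``."""
    x = np.zeros_like(t)
    rel_t = t - onset
    m = (rel_t >= 0) & (rel_t < press)
    x[m] = amp * 0.5 * (1 - np.cos(np.pi * rel_t[m] / press))
    m = (rel_t >= press) & (rel_t < press + dwell)
    x[m] = amp
    m = (rel_t >= press + dwell) & (rel_t <= press + dwell + release)
    x[m] = amp * 0.5 * (
        1 + np.cos(np.pi * (rel_t[m] - press - dwell) / release)
    )
    return x


def _tremor_windows(
    rng: np.random.Generator, duration: float, fraction: float
) -> List[Tuple[float, float]]:
    """Contiguous burst windows covering ~``fraction`` of the timeline."""
    if fraction <= 0:
        return []
    total = fraction * duration
    n_bursts = max(1, int(round(total / 3.0)))  # ~3 s bursts
    burst_len = total / n_bursts
    gaps = duration - total
    # place bursts with random gaps between them
    gap_weights = rng.random(n_bursts + 1)
    gap_weights /= gap_weights.sum()
    windows = []
    t = 0.0
    for i in range(n_bursts):
        t += gap_weights[i] * gaps
        windows.append((t, min(t + burst_len, duration)))
        t += burst_len
    return windows


def _in_window(t0: float, t1: float, windows) -> bool:
    return any(t0 >= a and t1 <= b for a, b in windows)


def _jitter(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    return max(mean * 0.2, rng.normal(mean, cv * mean))


def simulate_trace(
    profile: SimulationProfile,
) -> Tuple[RaftTrace, GroundTruth]:
    """Generate one trace plus its strike-level ground truth."""
    rng = np.random.default_rng(profile.seed)
    n = int(round(profile.duration * profile.sample_rate))
    t = np.arange(n) / profile.sample_rate
    channels = {"a": np.zeros(n), "b": np.zeros(n)}
    finger_map = {"a": "index", "b": "middle"}
    windows = _tremor_windows(rng, profile.duration, profile.tremor_fraction)
    gt: List[GroundTruthStrike] = []

    period = 1.0 / profile.tap_rate
    for k, ch in enumerate(("a", "b")):
        finger = finger_map[ch]
        onset = 0.05 + k * period / 2.0  # fingers half a cycle out of phase
        strike_idx = 0
        while True:
            span = (
                _jitter(rng, profile.press_duration, profile.phase_jitter_cv),
                _jitter(rng, profile.dwell_time, profile.phase_jitter_cv),
                _jitter(rng, profile.release_duration, profile.phase_jitter_cv),
            )
            end = onset + sum(span)
            if end >= profile.duration:
                break
            if _in_window(onset, min(onset + period, profile.duration),
                          windows):
                onset = _emit_tremor_run(
                    rng, profile, t, channels[ch], finger, ch, onset,
                    windows, gt,
                )
                strike_idx += 1  # decay clock keeps ticking during bursts
                continue
            amp = rng.normal(
                profile.press_depth_mean, profile.press_depth_sd
            ) * np.exp(-profile.depth_decay_rate * strike_idx)
            amp = float(np.clip(amp, 0.6, profile.device_max))
            channels[ch] += _strike_waveform(t, onset, amp, *span)
            gt.append(
                GroundTruthStrike(
                    finger=finger, channel=ch, onset=onset, amplitude=amp,
                    press_duration=span[0], dwell_time=span[1],
                    release_duration=span[2], tremor=False,
                )
            )
            strike_idx += 1
            gap = _jitter(rng, period, profile.isi_jitter_cv)
            onset += max(gap, sum(span) + 2.0 / profile.sample_rate)

    if profile.noise_sd > 0:
        for ch in channels:
            channels[ch] += rng.normal(0, profile.noise_sd, n)
    for ch in channels:
        channels[ch] = np.clip(channels[ch], 0.0, profile.device_max)

    trace = RaftTrace(
        sample_rate=profile.sample_rate,
        timestamps=t,
        channel_a=channels["a"],
        channel_b=channels["b"],
        finger_map=finger_map,
        hand=profile.hand,
        duration=profile.duration,
        device_max=profile.device_max,
    )
    return trace, GroundTruth(strikes=gt, tremor_windows=windows)


def _emit_tremor_run(
    rng, profile: SimulationProfile, t, channel, finger, ch, onset,
    windows, gt,
) -> float:
    """Fill the tremor window ahead of ``onset`` with oscillatory strikes.

    Tremor strikes tile the window at the tremor rate: 45% press, 45%
    release, 10% dwell of each tremor period, so their spans cover
    nearly the whole burst (that coverage is what rest-tremor % means).
    Returns the onset at which voluntary tapping resumes.
    """
    window_end = next(b for a, b in windows if a <= onset <= b)
    t_period = 1.0 / profile.tremor_rate
    press, dwell, release = 0.45 * t_period, 0.08 * t_period, 0.45 * t_period
    while onset + t_period <= window_end and (
        onset + t_period <= profile.duration
    ):
        amp = rng.normal(
            profile.tremor_amplitude_mean, profile.tremor_amplitude_sd
        )
        amp = float(np.clip(amp, 0.55, 0.3 * profile.device_max - 0.05))
        channel += _strike_waveform(t, onset, amp, press, dwell, release)
        gt.append(
            GroundTruthStrike(
                finger=finger, channel=ch, onset=onset, amplitude=amp,
                press_duration=press, dwell_time=dwell,
                release_duration=release, tremor=True,
            )
        )
        onset += t_period
    # resume voluntary tapping just past the window
    return max(onset, window_end) + 0.05


#: qualitative motor phenotypes used for cohort generation
PHENOTYPES: Dict[str, SimulationProfile] = {
    # brisk full-amplitude regular tapping
    "healthy": SimulationProfile(
        tap_rate=2.5,
        press_depth_mean=HEALTHY_PRESS_DEPTH_MEAN,
        press_depth_sd=HEALTHY_PRESS_DEPTH_SD,
        isi_jitter_cv=0.03,
        noise_sd=0.03,
    ),
    # low, decaying amplitude; slow press/release; slowed rate
    "bradykinetic": SimulationProfile(
        tap_rate=1.2,
        press_depth_mean=4.0,
        press_depth_sd=0.8,
        depth_decay_rate=0.02,
        isi_jitter_cv=0.15,
        press_duration=0.22,
        release_duration=0.25,
        dwell_time=0.12,
        noise_sd=0.03,
    ),
    # near-normal voluntary tapping with tremor bursts
    "tremor_dominant": SimulationProfile(
        tap_rate=2.2,
        press_depth_mean=8.0,
        press_depth_sd=0.4,
        isi_jitter_cv=0.08,
        tremor_fraction=0.25,
        tremor_rate=5.0,
        tremor_amplitude_mean=1.5,
        noise_sd=0.03,
    ),
    # moderate slowing plus tremor
    "mixed": SimulationProfile(
        tap_rate=1.6,
        press_depth_mean=5.5,
        press_depth_sd=0.9,
        depth_decay_rate=0.01,
        isi_jitter_cv=0.12,
        press_duration=0.16,
        release_duration=0.18,
        tremor_fraction=0.15,
        tremor_rate=4.5,
        tremor_amplitude_mean=1.2,
        noise_sd=0.03,
    ),
}


def phenotype_profile(
    name: str, seed: int, **overrides
) -> SimulationProfile:
    """A phenotype preset with a fresh seed and optional overrides."""
    if name not in PHENOTYPES:
        raise ValueError(
            f"unknown phenotype {name!r}; have {sorted(PHENOTYPES)}"
        )
    return replace(PHENOTYPES[name], seed=seed, **overrides)


def simulate_cohort(
    n_subjects: int,
    phenotype: str = "healthy",
    age_range: Tuple[float, float] = (45.0, 75.0),
    age_effect_slopes: Optional[Dict[str, float]] = None,
    seed: int = 0,
    hands: Tuple[str, ...] = ("L", "R"),
):
    """Simulate a cohort of subjects; returns (trial list, cohort table).

    Each subject gets one trace per hand drawn from the phenotype preset
    with mild between-subject variation.  ``age_effect_slopes`` maps a
    metric name to a linear drift in metric units per year, centred at
    age 60 and injected through the generator knob that controls it
    (``press_speed`` and ``release_slope`` via the phase durations,
    ``press_amplitude_cv`` via the depth SD).  The cohort table has one
    row per subject-hand with the extracted metrics, ready for
    :func:`qdg.normative.fit_reference`.
    """
    from .metrics import compute_metrics
    from .segmentation import SegmentationParams, segment_strikes
    from .tremor import label_strikes

    if n_subjects < 2:
        raise ValueError("cohort needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    base = PHENOTYPES[phenotype] if phenotype in PHENOTYPES else None
    if base is None:
        raise ValueError(
            f"unknown phenotype {phenotype!r}; have {sorted(PHENOTYPES)}"
        )
    slopes = age_effect_slopes or {}
    trials = []
    rows = []
    for i in range(n_subjects):
        age = float(rng.uniform(*age_range))
        subject_id = f"{phenotype[:3].upper()}{i:03d}"
        # between-subject variation of the preset
        subj_rate = base.tap_rate * float(rng.normal(1.0, 0.05))
        # between-subject spread dominates the trial-level amplitude
        # distribution (per-strike SD averages out over ~75 strikes)
        subj_depth = base.press_depth_mean + float(
            rng.normal(0.0, base.press_depth_sd)
        )
        phase_factor_p = float(rng.normal(1.0, 0.08))
        phase_factor_r = float(rng.normal(1.0, 0.08))
        press_dur = base.press_duration * phase_factor_p
        release_dur = base.release_duration * phase_factor_r
        subj_dwell = base.dwell_time * float(rng.normal(1.0, 0.10))
        subj_jitter = abs(float(rng.normal(base.isi_jitter_cv,
                                           0.3 * base.isi_jitter_cv)))
        if "press_speed" in slopes:
            base_speed = base.press_depth_mean / base.press_duration
            target = max(5.0, base_speed + slopes["press_speed"] * (age - 60.0))
            press_dur = subj_depth / target * phase_factor_p
        if "release_slope" in slopes:
            base_slope = base.press_depth_mean / base.release_duration
            target = max(
                5.0, base_slope + slopes["release_slope"] * (age - 60.0)
            )
            release_dur = subj_depth / target * phase_factor_r
        depth_sd = base.press_depth_sd
        if "press_amplitude_cv" in slopes:
            base_cv = base.press_depth_sd / base.press_depth_mean
            target_cv = max(
                1e-3, base_cv + slopes["press_amplitude_cv"] * (age - 60.0)
            )
            depth_sd = target_cv * subj_depth
        for hand in hands:
            profile = replace(
                base,
                seed=int(rng.integers(0, 2**31 - 1)),
                tap_rate=subj_rate,
                press_depth_mean=subj_depth,
                press_depth_sd=depth_sd,
                press_duration=press_dur,
                release_duration=release_dur,
                dwell_time=subj_dwell,
                isi_jitter_cv=subj_jitter,
                hand=hand,
            )
            trace, gt = simulate_trace(profile)
            seg = segment_strikes(
                trace, SegmentationParams(device_max_amplitude=profile.device_max)
            )
            label_strikes(seg, classifier=None, device_max=profile.device_max)
            m = compute_metrics(seg, trace)
            trials.append(
                {
                    "subject_id": subject_id,
                    "age": age,
                    "hand": hand,
                    "profile": profile,
                    "trace": trace,
                    "ground_truth": gt,
                    "segmentation": seg,
                    "metrics": m,
                }
            )
            rows.append(
                {
                    "subject_id": subject_id,
                    "age": age,
                    "hand": hand,
                    **m.hand,
                    "taps_per_minute": m.taps_per_minute,
                    "rest_tremor_pct": m.rest_tremor_pct,
                }
            )
    return trials, pd.DataFrame(rows)
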