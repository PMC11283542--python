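"""Composite QDG Mobility and Tremor Severity scores.

Mobility Score
--------------
Six metrics enter (ISI, ISI CV, press speed, press amplitude, press
amplitude CV, release slope).  Each raw z-score is oriented so that
larger means worse (the sign is flipped for lower-is-worse metrics) and
above-average performance is capped at 0.  Because healthy-control press
amplitudes cluster tightly around the full press (mean 8.67 mm, SD
0.12 mm), a moderately shallow press produces an enormous z that would
swamp the other five metrics; oriented press-amplitude z values above 10
(i.e. presses shallower than about 7.5 mm) are therefore compressed with
a power law

    z' = 3.2 * z**0.495          (identity for z <= 10, clipped at 20)

which is continuous at z = 10 to within 0.02.  The score is then

    Mobility = 100 - 14 * mean(z_oriented),  clamped to [0, 100]

so 100 is age-matched ideal performance and 0 a floor.

Tremor Severity Score
---------------------
Combines the percent of the trace occupied by tremor strikes with the
mean tremor amplitude normalised by the device maximum:

    Severity = (pct + 100 * f(pct) * meanAmp / ampMax) / 2

where f(pct) = 1 for pct >= 10 and f(pct) = 4**(0.05*pct) - 1 below 10%,
which smoothly suppresses the amplitude term for trials with barely any
tremor and equals 1 exactly at the 10% boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

from .metrics import TrialMetrics
from .normative import (
    MOBILITY_METRICS,
    NormativeReference,
    age_adjust,
    flag_abnormal,
    zscore,
)

PRESS_AMP_TRANSFORM_A = 3.2
PRESS_AMP_TRANSFORM_K = 0.495
PRESS_AMP_TRANSFORM_ACTIVATION = 10.0
PRESS_AMP_TRANSFORM_MAX = 20.0
MOBILITY_SCALE = 14.0
TREMOR_PCT_KNEE = 10.0  # % rest tremor below which amplitude is suppressed


@dataclass
class ScorePanel:
    """Oriented z-scores, composite scores and abnormality flags."""

    oriented_z: Dict[str, float]
    mobility_score: float
    tremor_severity: float
    transform_applied: bool
    flags: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "oriented_z": dict(self.oriented_z),
            "mobility_score": self.mobility_score,
            "tremor_severity": self.tremor_severity,
            "transform_applied": self.transform_applied,
            "flags": dict(self.flags),
        }


def orient_and_cap(
    raw_z: Dict[str, float], directions: Dict[str, str]
) -> Dict[str, float]:
    """Orient z-scores so larger = worse; cap above-average performance at 0.

    All six mobility metrics must be present.
    """
    missing = [m for m in MOBILITY_METRICS if m not in raw_z]
    if missing:
        raise ValueError(f"missing mobility metric z-scores: {missing}")
    out = {}
    for m in MOBILITY_METRICS:
        z = raw_z[m]
        oriented = -z if directions[m] == "lower_worse" else z
        out[m] = max(0.0, oriented)
    return out


def transform_press_amp_z(oriented_z: float) -> float:
    """Power-law compression of large oriented press-amplitude z values.

    Identity up to the activation threshold of 10; above it
    ``3.2 * z**0.495``, never exceeding 20.
    """
    if oriented_z < 0:
        raise ValueError("oriented z must be non-negative")
    if oriented_z <= PRESS_AMP_TRANSFORM_ACTIVATION:
        return oriented_z
    return min(
        PRESS_AMP_TRANSFORM_MAX,
        PRESS_AMP_TRANSFORM_A * oriented_z**PRESS_AMP_TRANSFORM_K,
    )


def mobility_score(oriented_z: Dict[str, float]) -> float:
    """100 - 14 * mean of the six oriented z-scores, clamped to [0, 100]."""
    if set(oriented_z) != set(MOBILITY_METRICS):
        raise ValueError(
            f"mobility score needs exactly the six metrics "
            f"{sorted(MOBILITY_METRICS)}, got {sorted(oriented_z)}"
        )
    mean_z = sum(oriented_z.values()) / len(oriented_z)
    return min(100.0, max(0.0, 100.0 - MOBILITY_SCALE * mean_z))


def tremor_severity(
    rest_tremor_pct: float,
    mean_tremor_amplitude: float,
    amp_max: float = 10.0,
) -> float:
    """Composite 0-100 tremor severity from duration and amplitude.

    Below 10% tremor the normalised-amplitude term is multiplied by
    ``4**(0.05*pct) - 1``, which vanishes as pct -> 0 and reaches 1 at
    the 10% knee, keeping the score continuous there.
    """
    if not 0.0 <= rest_tremor_pct <= 100.0:
        raise ValueError("rest_tremor_pct must lie in [0, 100]")
    if mean_tremor_amplitude > amp_max:
        raise ValueError(
            f"mean tremor amplitude {mean_tremor_amplitude} exceeds device "
            f"maximum {amp_max}"
        )
    norm_amp = mean_tremor_amplitude / amp_max
    if rest_tremor_pct < TREMOR_PCT_KNEE:
        rt_amp = 4.0 ** (0.05 * rest_tremor_pct) - 1.0
        amp_term = 100.0 * rt_amp * norm_amp
    else:
        amp_term = 100.0 * norm_amp
    return min(100.0, max(0.0, (rest_tremor_pct + amp_term) / 2.0))


def score_panel(
    trial: TrialMetrics,
    age: float,
    ref: NormativeReference,
    mean_tremor_amplitude: float = 0.0,
    amp_max: float = 10.0,
) -> ScorePanel:
    """Full scoring of one trial: z-scores, both composites, flags."""
    raw_z = {}
    adjusted = {}
    for m in MOBILITY_METRICS:
        adj = age_adjust(trial.hand[m], age, ref, m)
        adjusted[m] = adj
        raw_z[m] = zscore(adj, ref, m)
    directions = {m: ref[m].direction for m in MOBILITY_METRICS}
    oriented = orient_and_cap(raw_z, directions)
    transformed = transform_press_amp_z(oriented["press_amplitude"])
    transform_applied = transformed != oriented["press_amplitude"]
    oriented["press_amplitude"] = transformed
    mob = mobility_score(oriented)
    sev = tremor_severity(
        trial.rest_tremor_pct, mean_tremor_amplitude, amp_max
    )
    flags = {
        m: flag_abnormal(adjusted[m], ref, m) for m in MOBILITY_METRICS
    }
    for extra in ("taps_per_minute", "rest_tremor_pct", "dwell_time"):
        if extra in ref.metrics:
            value = getattr(trial, extra, None)
            if value is None:
                value = trial.hand.get(extra)
            if value is not None:
                flags[extra] = flag_abnormal(value, ref, extra)
    return ScorePanel(
        oriented_z=oriented,
        mobility_score=mob,
        tremor_severity=sev,
        transform_applied=transform_applied,
        flags=flags,
    )
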