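"""Healthy-control normative reference: age adjustment, z-scores, flags.

Each metric is referenced against the healthy-control (HC) cohort
distribution.  For the metrics with a demonstrable age trend (press
amplitude CV, release slope, press speed) a linear age effect is fitted
with a mixed model (random intercept per subject, fixed age effect;
plain OLS on subject means is the fallback when the mixed fit is
degenerate) and values are adjusted to a common reference age of 60:

    adjusted = value + slope * (age - 60)

The normative mean/SD are computed on the age-adjusted HC values, so an
incoming trial's z-score is

    z = (adjusted - mean) / sd.

Abnormality thresholds are percentiles of the adjusted HC distribution:
the 25th for metrics where lower is worse (press amplitude, press speed,
release slope, taps per minute, Mobility Score) and the 75th where
higher is worse (ISI, ISI CV, press amplitude CV, dwell time, rest
tremor %).  The boundary itself counts as normal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

REFERENCE_AGE = 60.0

#: orientation of every scored / flagged quantity
DIRECTIONS: Dict[str, str] = {
    "press_amplitude": "lower_worse",
    "press_speed": "lower_worse",
    "release_slope": "lower_worse",
    "taps_per_minute": "lower_worse",
    "mobility_score": "lower_worse",
    "isi": "higher_worse",
    "isi_cv": "higher_worse",
    "press_amplitude_cv": "higher_worse",
    "dwell_time": "higher_worse",
    "rest_tremor_pct": "higher_worse",
}

#: metrics with a fitted linear age effect
AGE_AFFECTED = ("press_amplitude_cv", "release_slope", "press_speed")

#: the six metrics entering the Mobility Score
MOBILITY_METRICS = (
    "isi",
    "isi_cv",
    "press_speed",
    "press_amplitude",
    "press_amplitude_cv",
    "release_slope",
)

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class MetricReference:
    mean: float
    sd: float
    age_slope: float
    direction: str
    threshold_value: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError("reference sd must be positive")
        if self.direction not in ("lower_worse", "higher_worse"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class NormativeReference:
    """Per-metric normative parameters fitted from a HC cohort."""

    metrics: Dict[str, MetricReference]
    reference_age: float = REFERENCE_AGE
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, metric: str) -> MetricReference:
        try:
            return self.metrics[metric]
        except KeyError:
            raise KeyError(
                f"metric {metric!r} not in normative reference "
                f"(have {sorted(self.metrics)})"
            ) from None

    def to_json(self, path) -> None:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "reference_age": self.reference_age,
            "provenance": self.provenance,
            "metrics": {
                k: {
                    "mean": r.mean,
                    "sd": r.sd,
                    "age_slope": r.age_slope,
                    "direction": r.direction,
                    "threshold_value": r.threshold_value,
                }
                for k, r in self.metrics.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "NormativeReference":
        payload = json.loads(Path(path).read_text())
        return cls(
            metrics={
                k: MetricReference(**v) for k, v in payload["metrics"].items()
            },
            reference_age=payload["reference_age"],
            provenance=payload.get("provenance", {}),
        )


def _fit_age_slope(df: pd.DataFrame, metric: str) -> float:
    """Mixed model (random intercept per subject) fixed age effect.

    Falls back to OLS on per-subject means when the mixed fit cannot
    converge (e.g. one observation per subject).
    """
    data = df[["subject_id", "age", metric]].dropna()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(
                f"{metric} ~ age", data, groups=data["subject_id"]
            )
            fit = md.fit(reml=True, method="lbfgs")
        slope = float(fit.params["age"])
        if np.isfinite(slope):
            return slope
    except Exception:
        pass
    means = data.groupby("subject_id").agg({metric: "mean", "age": "mean"})
    X = sm.add_constant(means["age"].to_numpy())
    ols = sm.OLS(means[metric].to_numpy(), X).fit()
    return float(ols.params[1])


def fit_reference(
    hc: pd.DataFrame,
    age_affected: Iterable[str] = AGE_AFFECTED,
    directions: Dict[str, str] = DIRECTIONS,
    metrics: Iterable[str] | None = None,
) -> NormativeReference:
    """Fit the normative reference from a healthy-control cohort table.

    ``hc`` needs columns ``subject_id``, ``age``, ``hand`` and one
    column per metric.  ``metrics`` restricts which columns are fitted
    (default: every known metric present in the table).  Thresholds are
    computed on the age-adjusted values, consistently with z-scoring.
    A constant metric column is an error naming the metric — e.g. the
    identically-zero rest-tremor column of a tremor-free cohort, which
    cannot define a distribution and should be excluded via ``metrics``.
    """
    required = {"subject_id", "age"}
    missing = required - set(hc.columns)
    if missing:
        raise ValueError(f"HC table missing columns: {sorted(missing)}")
    if hc["subject_id"].nunique() < 2:
        raise ValueError("HC table needs at least 2 subjects")
    if (hc["age"] <= 0).any():
        raise ValueError("HC ages must be positive")
    age_affected = set(age_affected)
    wanted = set(metrics) if metrics is not None else None
    refs: Dict[str, MetricReference] = {}
    for metric in directions:
        if metric not in hc.columns:
            continue
        if wanted is not None and metric not in wanted:
            continue
        col = hc[metric].dropna()
        if col.nunique() <= 1:
            raise ValueError(
                f"HC metric column {metric!r} is constant; cannot form a "
                "normative distribution"
            )
        slope = _fit_age_slope(hc, metric) if metric in age_affected else 0.0
        adjusted = hc[metric] + slope * (hc["age"] - REFERENCE_AGE)
        adjusted = adjusted.dropna().to_numpy()
        direction = directions[metric]
        pct = 25 if direction == "lower_worse" else 75
        refs[metric] = MetricReference(
            mean=float(adjusted.mean()),
            sd=float(adjusted.std(ddof=1)),
            age_slope=float(slope),
            direction=direction,
            threshold_value=float(np.percentile(adjusted, pct)),
        )
    return NormativeReference(
        metrics=refs,
        provenance={
            "n_subjects": int(hc["subject_id"].nunique()),
            "n_rows": int(len(hc)),
        },
    )


def age_adjust(
    value: float, age: float, ref: NormativeReference, metric: str
) -> float:
    """Adjust a metric value to the reference age via the linear age slope.

    Identity for metrics with zero slope and for subjects at the
    reference age.
    """
    r = ref[metric]
    return value + r.age_slope * (age - ref.reference_age)


def zscore(value: float, ref: NormativeReference, metric: str) -> float:
    """Standard score of an (age-adjusted) value against the HC reference."""
    r = ref[metric]
    return (value - r.mean) / r.sd


def flag_abnormal(
    value: float, ref: NormativeReference, metric: str
) -> str:
    """``"normal"`` or ``"abnormal"`` against the HC percentile threshold.

    The threshold itself is normal (inclusive boundary).
    """
    r = ref[metric]
    if r.direction == "lower_worse":
        return "abnormal" if value < r.threshold_value else "normal"
    return "abnormal" if value > r.threshold_value else "normal"
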