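"""Per-strike tremor classification.

Rest tremor in a tapping trace appears as runs of low-amplitude strikes
at 3-8 Hz, interleaved with (or replacing) the voluntary full presses at
the self-paced tapping rate.  Two classifiers are provided behind one
interface:

* a deterministic rule — tremor iff the instantaneous strike rate is at
  least ``rate_min`` Hz AND the amplitude is below ``amplitude_ratio_max``
  of the device maximum — which needs no training data; and
* a gradient-boosted (XGBoost) classifier trained on simulator-labelled
  strikes, serialisable with its training provenance.

Feature extraction is shared: each strike contributes its kinematics
plus finger-local ISI context (the first strike of a finger has no
preceding interval, hence missing rate features).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import train_test_split

from .segmentation import SegmentationResult, StrikeEvent

FEATURE_COLUMNS = (
    "press_amplitude",
    "isi_prev",
    "instantaneous_rate",
    "press_speed",
    "release_slope",
    "dwell_time",
    "amplitude_ratio",
)


def extract_strike_features(
    strikes_by_finger: Dict[str, List[StrikeEvent]],
    device_max: float = 10.0,
) -> pd.DataFrame:
    """One feature row per strike, in within-finger onset order.

    ``isi_prev`` and ``instantaneous_rate`` are finger-local; they are
    NaN for the first strike of each finger.
    """
    rows = []
    for finger, strikes in strikes_by_finger.items():
        prev_onset = None
        for s in sorted(strikes, key=lambda s: s.onset_t):
            isi_prev = (
                s.onset_t - prev_onset if prev_onset is not None else np.nan
            )
            rows.append(
                {
                    "finger": finger,
                    "onset_t": s.onset_t,
                    "press_amplitude": s.press_amplitude,
                    "isi_prev": isi_prev,
                    "instantaneous_rate": (
                        1.0 / isi_prev if isi_prev and isi_prev > 0 else np.nan
                    ),
                    "press_speed": s.press_speed,
                    "release_slope": s.release_slope,
                    "dwell_time": s.dwell_time,
                    "amplitude_ratio": s.press_amplitude / device_max,
                }
            )
            prev_onset = s.onset_t
    return pd.DataFrame(
        rows,
        columns=["finger", "onset_t", *FEATURE_COLUMNS],
    )


def rule_classify(
    features: pd.DataFrame,
    rate_min: float = 3.0,
    amplitude_ratio_max: float = 0.3,
) -> np.ndarray:
    """Deterministic fallback rule: fast AND small strikes are tremor.

    First strikes (no instantaneous rate) default to voluntary.
    """
    rate = features["instantaneous_rate"].to_numpy()
    ratio = features["amplitude_ratio"].to_numpy()
    with np.errstate(invalid="ignore"):
        out = (rate >= rate_min) & (ratio < amplitude_ratio_max)
    return np.where(np.isnan(rate), False, out)


@dataclass
class TremorModel:
    """A fitted per-strike tremor classifier with training provenance.

    Wraps the boosted-tree ensemble at booster level so the model file
    is a plain JSON artifact independent of the training-time wrapper.
    """

    booster: xgb.Booster
    provenance: dict
    threshold: float = 0.5

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        X = features[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        return self.booster.predict(
            xgb.DMatrix(X, feature_names=list(FEATURE_COLUMNS))
        )

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.predict_proba(features) >= self.threshold

    def save(self, path) -> None:
        path = Path(path)
        self.booster.save_model(str(path))
        meta = {"provenance": self.provenance, "threshold": self.threshold}
        Path(str(path) + ".meta.json").write_text(
            json.dumps(meta, indent=1, sort_keys=True)
        )

    @classmethod
    def load(cls, path) -> "TremorModel":
        booster = xgb.Booster()
        booster.load_model(str(path))
        meta = json.loads(Path(str(path) + ".meta.json").read_text())
        return cls(
            booster=booster,
            provenance=meta["provenance"],
            threshold=meta["threshold"],
        )


def train_tremor_classifier(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    test_size: float = 0.2,
    provenance: Optional[dict] = None,
) -> tuple[TremorModel, float]:
    """Train the gradient-boosted per-strike classifier.

    Returns ``(model, held_out_balanced_accuracy)``.  Training is
    deterministic given ``seed``.  Raises ``ValueError`` if only one
    class is present.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError(
            "training data must contain both tremor and voluntary strikes"
        )
    X = features[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, labels, test_size=test_size, random_state=seed, stratify=labels
    )
    clf = xgb.XGBClassifier(
        n_estimators=100,
        max_depth=4,
        learning_rate=0.2,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )
    clf.fit(X_tr, y_tr)
    bal_acc = balanced_accuracy_score(y_te, clf.predict(X_te))
    booster = clf.get_booster()
    booster.feature_names = list(FEATURE_COLUMNS)
    model = TremorModel(
        booster=booster,
        provenance={
            "seed": seed,
            "n_strikes": int(len(labels)),
            "n_tremor": int(labels.sum()),
            "held_out_balanced_accuracy": float(bal_acc),
            **(provenance or {}),
        },
    )
    return model, float(bal_acc)


def label_strikes(
    segmentation: SegmentationResult,
    classifier=None,
    device_max: float = 10.0,
) -> SegmentationResult:
    """Set the ``tremor`` flag on every strike, in place.

    ``classifier`` is either a :class:`TremorModel` or ``None`` for the
    deterministic rule.
    """
    feats = extract_strike_features(segmentation.strikes, device_max)
    if feats.empty:
        return segmentation
    if classifier is None:
        pred = rule_classify(feats)
    else:
        pred = classifier.predict(feats)
    # rows are ordered finger-by-finger, onset-sorted, matching extraction
    i = 0
    for finger in segmentation.strikes:
        for s in sorted(
            segmentation.strikes[finger], key=lambda s: s.onset_t
        ):
            s.tremor = bool(pred[i])
            i += 1
    return segmentation


def tremor_amplitude_stats(
    strikes: List[StrikeEvent], duration: float
) -> tuple[float, float, int]:
    """(rest_tremor_pct, mean tremor amplitude in mm, tremor strike count).

    With no tremor strikes the mean amplitude is 0 (it then contributes
    nothing to the severity score).
    """
    from .metrics import tremor_coverage_pct

    tremor = [s for s in strikes if s.tremor]
    pct = tremor_coverage_pct(strikes, duration)
    mean_amp = (
        float(np.mean([s.press_amplitude for s in tremor])) if tremor else 0.0
    )
    return pct, mean_amp, len(tremor)
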