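"""Shared fixtures: simulated traces, labelled strike sets, HC reference.

Everything is generated programmatically from the simulator with fixed
seeds; session scope keeps the suite fast.
"""

import numpy as np
import pandas as pd
import pytest

from qdg.metrics import compute_metrics
from qdg.normative import fit_reference
from qdg.segmentation import segment_strikes
from qdg.simulate import phenotype_profile, simulate_cohort, simulate_trace
from qdg.tremor import extract_strike_features, label_strikes

#: metrics fit into the test reference (rest tremor is identically zero
#: in a healthy cohort and cannot define a distribution)
SCORABLE_METRICS = [
    "press_amplitude",
    "press_amplitude_cv",
    "isi",
    "isi_cv",
    "press_speed",
    "release_slope",
    "dwell_time",
    "taps_per_minute",
]


def truth_labels_for(features: pd.DataFrame, ground_truth) -> np.ndarray:
    """Ground-truth tremor label for each detected strike, by onset match."""
    gts = sorted(ground_truth.strikes, key=lambda s: s.onset)
    onsets = np.array([g.onset for g in gts])
    labels = np.array([g.tremor for g in gts])
    out = []
    for o in features["onset_t"].to_numpy():
        k = int(np.argmin(np.abs(onsets - o)))
        out.append(bool(labels[k]) if abs(onsets[k] - o) < 0.06 else False)
    return np.array(out)


@pytest.fixture(scope="session")
def healthy_trace():
    profile = phenotype_profile("healthy", seed=101)
    return simulate_trace(profile)


@pytest.fixture(scope="session")
def tremor_trace():
    profile = phenotype_profile("tremor_dominant", seed=202)
    return simulate_trace(profile)


@pytest.fixture(scope="session")
def hc_reference():
    """Normative reference fitted on a small simulated healthy cohort."""
    _, table = simulate_cohort(16, "healthy", seed=7)
    return fit_reference(table, metrics=SCORABLE_METRICS)


@pytest.fixture(scope="session")
def labelled_strikes():
    """Strike features + ground-truth tremor labels across phenotypes."""
    feats, labels = [], []
    phenos = (
        ["tremor_dominant"] * 12 + ["mixed"] * 12 + ["healthy"] * 10
        + ["bradykinetic"] * 6
    )
    for i, ph in enumerate(phenos):
        trace, gt = simulate_trace(phenotype_profile(ph, seed=300 + i))
        seg = segment_strikes(trace)
        f = extract_strike_features(seg.strikes, trace.device_max)
        feats.append(f)
        labels.append(truth_labels_for(f, gt))
    return pd.concat(feats, ignore_index=True), np.concatenate(labels)


@pytest.fixture(scope="session")
def scored_trial(hc_reference):
    """A segmented, labelled, measured healthy trial."""
    trace, gt = simulate_trace(phenotype_profile("healthy", seed=404))
    seg = segment_strikes(trace)
    label_strikes(seg)
    return trace, gt, seg, compute_metrics(seg, trace)
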