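"""End-to-end convenience: raw trace -> metrics -> score panel."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .metrics import TrialMetrics, compute_metrics
from .normative import NormativeReference
from .scoring import ScorePanel, score_panel
from .segmentation import SegmentationParams, SegmentationResult, segment_strikes
from .trace import QCReport, RaftTrace, TrialMetadata, qc_screen
from .tremor import label_strikes, tremor_amplitude_stats


@dataclass
class AnalysisResult:
    qc: QCReport
    segmentation: Optional[SegmentationResult]
    metrics: Optional[TrialMetrics]
    panel: Optional[ScorePanel]


def analyze_trace(
    trace: RaftTrace,
    meta: TrialMetadata,
    reference: Optional[NormativeReference] = None,
    tremor_classifier=None,
    params: Optional[SegmentationParams] = None,
    enforce_qc: bool = True,
) -> AnalysisResult:
    """Run QC, segmentation, tremor labelling, metrics and scoring.

    When QC fails and ``enforce_qc`` is set, analysis stops after the
    screen (the device flow asks the user to redo the test).  Scoring
    requires a normative ``reference``; without one the result stops at
    the metrics.
    """
    qc = qc_screen(trace)
    if enforce_qc and not qc.passed:
        return AnalysisResult(qc=qc, segmentation=None, metrics=None, panel=None)
    seg = segment_strikes(trace, params)
    label_strikes(seg, classifier=tremor_classifier, device_max=trace.device_max)
    metrics = compute_metrics(seg, trace)
    panel = None
    if reference is not None:
        _, mean_amp, _ = tremor_amplitude_stats(
            seg.all_strikes(), trace.duration
        )
        panel = score_panel(
            metrics,
            age=meta.age,
            ref=reference,
            mean_tremor_amplitude=mean_amp,
            amp_max=trace.device_max,
        )
    return AnalysisResult(qc=qc, segmentation=seg, metrics=metrics, panel=panel)
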