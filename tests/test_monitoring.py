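"""Monitoring analytics: compliance, adherence, trends, report export."""

import numpy as np
import pytest

from qdg.monitoring import (
    SessionRecord,
    adherence_summary,
    cohort_compliance,
    compliance_summary,
    read_session_store,
    render_report,
    trend_slope,
    write_session_store,
)
from qdg.trace import TherapyContext

MARCH = ("2024-03-01", "2024-03-30")


def day_times(days, per_day=1, month="2024-03"):
    return [
        f"{month}-{d:02d}T{8 + k * 6:02d}:00"
        for d in days
        for k in range(per_day)
    ]


class TestCompliance:
    def test_sixteen_days_meets_criterion(self):
        s = compliance_summary(day_times(range(1, 17)), MARCH)
        assert s.days_tested == 16
        assert s.compliance_ratio == pytest.approx(16 / 30, abs=5e-4)
        assert s.meets_16_of_30

    def test_fifteen_days_fails(self):
        s = compliance_summary(day_times(range(1, 16)), MARCH)
        assert not s.meets_16_of_30

    def test_same_day_tests_count_once(self):
        s = compliance_summary(day_times([5, 5, 6]), MARCH)
        assert s.days_tested == 2
        assert s.twice_daily_days == 1

    def test_ratio_invariant_to_intraday_multiplicity(self):
        once = compliance_summary(day_times(range(1, 20)), MARCH)
        thrice = compliance_summary(
            day_times(range(1, 20), per_day=3), MARCH
        )
        assert once.compliance_ratio == thrice.compliance_ratio

    def test_records_outside_window_ignored(self):
        s = compliance_summary(
            day_times(range(1, 17)) + ["2024-04-02T09:00"], MARCH
        )
        assert s.days_tested == 16

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            compliance_summary([], ("2024-03-10", "2024-03-01"))


class TestCohortCompliance:
    def _trial_pattern(self):
        """Eight subjects mirroring the pilot trial: all test on at least
        16 days; seven of them twice daily, the eighth only once."""
        summaries = []
        for i in range(7):
            summaries.append(
                compliance_summary(
                    day_times(range(1, 18 + i), per_day=2), MARCH
                )
            )
        summaries.append(
            compliance_summary(day_times(range(1, 21), per_day=1), MARCH)
        )
        return summaries

    def test_all_meet_once_daily(self):
        assert cohort_compliance(self._trial_pattern()) == 1.0

    def test_seven_of_eight_meet_twice_daily(self):
        frac = cohort_compliance(self._trial_pattern(), twice_daily=True)
        assert frac == pytest.approx(7 / 8)

    def test_none_meeting(self):
        summaries = [compliance_summary(day_times([1, 2]), MARCH)]
        assert cohort_compliance(summaries) == 0.0


class TestAdherence:
    CTX = TherapyContext(
        prescribed_doses=(
            ("2024-03-05T08:00", "levodopa"),
            ("2024-03-05T12:00", "levodopa"),
            ("2024-03-05T16:00", "levodopa"),
        ),
        taken_doses=(
            ("2024-03-05T08:20", "levodopa"),
            ("2024-03-05T12:05", "levodopa"),
        ),
    )

    def test_delta_minutes(self):
        matches = adherence_summary(self.CTX, "2024-03-05")
        assert matches[0].delta_minutes == pytest.approx(20.0)
        assert matches[1].delta_minutes == pytest.approx(5.0)

    def test_unmatched_dose_flagged_missed(self):
        matches = adherence_summary(self.CTX, "2024-03-05")
        assert [m.missed for m in matches] == [False, False, True]

    def test_empty_taken_all_missed(self):
        ctx = TherapyContext(prescribed_doses=self.CTX.prescribed_doses)
        assert all(m.missed for m in adherence_summary(ctx, "2024-03-05"))

    def test_match_window_enforced(self):
        ctx = TherapyContext(
            prescribed_doses=(("2024-03-05T08:00", "levodopa"),),
            taken_doses=(("2024-03-05T14:00", "levodopa"),),
        )
        (m,) = adherence_summary(ctx, "2024-03-05")
        assert m.missed


class TestTrendSlope:
    def test_exact_line(self):
        days = np.arange(1, 11, dtype=float)
        t = trend_slope(days, 90 - 1.0 * days)
        assert t.slope == pytest.approx(-1.0)
        assert t.p_value < 1e-10

    def test_constant_series(self):
        days = np.arange(1, 11, dtype=float)
        rng = np.random.default_rng(3)
        t = trend_slope(days, 80 + rng.normal(0, 1, 10))
        assert t.ci95[0] < 0 < t.ci95[1]

    def test_closed_form_ols_equivalence(self):
        """Slope and CI match the textbook least-squares formulas."""
        rng = np.random.default_rng(7)
        days = np.arange(1, 27, dtype=float)
        y = 95 - 1.18 * days + rng.normal(0, 9.5, 26)
        t = trend_slope(days, y)
        xc = days - days.mean()
        slope = float(xc @ (y - y.mean()) / (xc @ xc))
        resid = y - (y.mean() + slope * xc)
        se = np.sqrt(resid @ resid / (len(days) - 2) / (xc @ xc))
        from scipy import stats

        half = stats.t.ppf(0.975, len(days) - 2) * se
        assert t.slope == pytest.approx(slope, abs=1e-10)
        assert t.ci95[0] == pytest.approx(slope - half, abs=1e-8)
        assert t.ci95[1] == pytest.approx(slope + half, abs=1e-8)
        assert t.ci95[0] < t.slope < t.ci95[1]

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError):
            trend_slope([1, 2], [3, 4])


def make_record(day, score=85.0, flag_metric_value=8.6):
    return SessionRecord(
        subject_id="P01",
        test_time=f"2024-03-{day:02d}T09:00:00",
        hand="R",
        therapy_state="on",
        metrics={
            "hand": {
                "press_amplitude": flag_metric_value,
                "isi": 0.4,
                "isi_cv": 0.05,
                "press_speed": 80.0,
                "press_amplitude_cv": 0.05,
                "release_slope": 100.0,
                "dwell_time": 0.06,
            },
            "taps_per_minute": 290.0,
            "rest_tremor_pct": 0.0,
        },
        scores={"mobility_score": score, "tremor_severity": 0.0},
    )


class TestRenderReport:
    def test_panel_structure(self, hc_reference):
        records = [make_record(d) for d in range(1, 11)]
        doc = render_report(records, hc_reference)
        tiles = doc["single_test_panel"]["metric_tiles"]
        assert len(tiles) >= 6
        assert doc["monthly_panel"]["n_tests"] == 10
        assert len(doc["daily_panel"]["mobility_score"]) == 10

    def test_abnormal_value_flagged(self, hc_reference):
        low = hc_reference["press_amplitude"].threshold_value - 1.0
        doc = render_report([make_record(1, flag_metric_value=low)],
                            hc_reference)
        tile = doc["single_test_panel"]["metric_tiles"]["press_amplitude"]
        assert tile["flag"] == "abnormal"

    def test_json_round_trip_store(self, tmp_path):
        records = [make_record(d) for d in (1, 2, 3)]
        path = tmp_path / "sessions.jsonl"
        write_session_store(records, path)
        back = read_session_store(path)
        assert back == records
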