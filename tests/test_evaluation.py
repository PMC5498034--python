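"""Sensitivity, specificity, FP-per-hour, event matching and pooled reports."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fallkit as fk
from fallkit.evaluation import EvalResult, format_hours, report_rows

from conftest import ThresholdModel, steps_stream


class TestMetricPrimitives:
    @pytest.mark.parametrize(
        "tp,fn,expected",
        [(8, 2, 0.80), (7, 2, 7 / 9), (1, 0, 1.0), (0, 3, 0.0)],
    )
    def test_sensitivity(self, tp, fn, expected):
        assert fk.sensitivity(tp, fn) == pytest.approx(expected)

    def test_sensitivity_undefined_without_falls(self):
        assert fk.sensitivity(0, 0) is None

    @pytest.mark.parametrize(
        "tn,fp,expected", [(10, 0, 1.0), (9999, 1, 0.9999), (0, 5, 0.0)]
    )
    def test_specificity(self, tn, fp, expected):
        assert fk.specificity(tn, fp) == pytest.approx(expected)

    def test_specificity_undefined_without_negatives(self):
        assert fk.specificity(0, 0) is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fk.sensitivity(-1, 0)
        with pytest.raises(ValueError):
            fk.specificity(0, -1)

    @pytest.mark.parametrize(
        "fp,duration,expected_2dp",
        [
            (10, "214:00:15", 0.05),
            (4, "14:37:58", 0.27),
            (26, "172:12:04", 0.15),
            (7, "23:33:41", 0.30),
            (0, "100:00:00", 0.00),
        ],
    )
    def test_fp_rate_from_hhmmss(self, fp, duration, expected_2dp):
        assert round(fk.fp_rate(fp, duration), 2) == pytest.approx(expected_2dp)

    def test_duration_parsing(self):
        assert fk.parse_duration("2:30:00") == pytest.approx(2.5)
        assert fk.parse_duration(3.25) == 3.25
        with pytest.raises(ValueError):
            fk.parse_duration("90:00")
        with pytest.raises(ValueError):
            fk.fp_rate(1, "0:00:00")

    @pytest.mark.parametrize("text", ["214:00:15", "5:32:54", "0:00:01"])
    def test_format_hours_inverts_parse(self, text):
        assert format_hours(fk.parse_duration(text)) == text


class TestMatchEvents:
    def test_empty_inputs(self):
        assert fk.match_events([], []) == (0, 0, 0, [])

    def test_detection_within_tolerance_is_tp(self):
        tp, fp, fn, pairs = fk.match_events([100.0], [95.0], tol_s=20.0)
        assert (tp, fp, fn) == (1, 0, 0)
        assert pairs == [(0, 0)]

    def test_two_detections_one_annotation(self):
        tp, fp, fn, _ = fk.match_events([94.0, 101.0], [95.0], tol_s=20.0)
        assert (tp, fp, fn) == (1, 1, 0)

    def test_outside_tolerance_is_fp_and_fn(self):
        tp, fp, fn, _ = fk.match_events([100.0], [50.0], tol_s=20.0)
        assert (tp, fp, fn) == (0, 1, 1)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            fk.match_events([], [], tol_s=-1.0)

    @settings(max_examples=60, deadline=None)
    @given(
        det=st.lists(st.floats(0, 500), max_size=5),
        ann=st.lists(st.floats(0, 500), max_size=5),
        tol=st.sampled_from([5.0, 20.0, 60.0]),
    )
    def test_agrees_with_exhaustive_greedy_replay(self, det, ann, tol):
        det, ann = sorted(det), sorted(ann)
        tp, fp, fn, pairs = fk.match_events(det, ann, tol)
        # exhaustive replay: repeatedly pick the globally closest feasible pair
        remaining_d = dict(enumerate(det))
        remaining_a = dict(enumerate(ann))
        expected = []
        while True:
            feasible = [
                (abs(d - a), i, j)
                for i, d in remaining_d.items()
                for j, a in remaining_a.items()
                if abs(d - a) <= tol
            ]
            if not feasible:
                break
            _, i, j = min(feasible)
            expected.append((i, j))
            del remaining_d[i], remaining_a[j]
        assert sorted(pairs) == sorted(expected)
        assert tp == len(expected)
        assert tp + fp == len(det)
        assert tp + fn == len(ann)


class TestEvaluate:
    def _subjects(self):
        # subject A: one annotated fall, detected; subject B: quiet, no falls
        a = steps_stream("0" * 30 + "111" + "0" * 57)  # 90 s
        b = steps_stream("0" * 180)  # 180 s
        return [
            ("A", a, [fk.FallAnnotation(31.0)]),
            ("B", b, []),
        ]

    def test_per_subject_and_pooled(self, threshold_model):
        results = fk.evaluate(self._subjects(), threshold_model, tol_s=20.0)
        byname = {r.subject: r for r in results}
        assert byname["A"].true_pos == 1 and byname["A"].false_neg == 0
        assert byname["B"].sensitivity is None
        assert byname["B"].specificity == 1.0
        assert byname["B"].fp_rate == 0.0
        pooled = byname["Total"]
        assert pooled.true_pos == 1
        assert pooled.monitored_hours == pytest.approx(270 / 3600)

    def test_pooled_rate_is_count_ratio_not_mean_of_rates(self):
        r1 = EvalResult("a", 0, 0, 2, 100, 1.0)   # 2 FP/hr
        r2 = EvalResult("b", 0, 0, 0, 100, 3.0)   # 0 FP/hr
        pooled = EvalResult("Total", 0, 0, 2, 200, 4.0)
        assert pooled.fp_rate == pytest.approx(0.5)  # 2/4, not mean(2,0)=1
        assert pooled.fp_rate != pytest.approx((r1.fp_rate + r2.fp_rate) / 2)

    def test_annotation_outside_stream_rejected(self, threshold_model):
        stream = steps_stream("0" * 60)
        with pytest.raises(ValueError, match="outside"):
            fk.evaluate_subject("x", stream, [fk.FallAnnotation(1000.0)], threshold_model)

    def test_tn_excludes_annotation_neighborhood_and_suppressed(self, threshold_model):
        stream = steps_stream("0" * 30 + "111" + "0" * 57)
        result, events = fk.evaluate_subject(
            "x", stream, [fk.FallAnnotation(31.0)], threshold_model, tol_s=20.0
        )
        assert result.true_pos == 1
        # evaluated windows: starts 0..87; windows fully outside ann±20 and
        # not fall-labeled and not suppressed count as TN
        assert 0 < result.true_neg < 88

    def test_counting_identities(self, quick_model):
        stream, anns = fk.generate_stream(300.0, [150.0], rng=np.random.default_rng(3))
        result, events = fk.evaluate_subject("s", stream, anns, quick_model)
        assert result.true_pos + result.false_neg == len(anns)
        assert result.true_pos + result.false_pos == len(events)
        for frac in (result.sensitivity, result.specificity):
            if frac is not None:
                assert 0.0 <= frac <= 1.0
        assert result.fp_rate >= 0.0


class TestReport:
    def test_rows_round_percentages_and_mark_undefined(self, tmp_path):
        results = [
            EvalResult("Resident 5", 0, 0, 0, 500, 5.548),
            EvalResult("Resident 4", 0, 0, 4, 39996, fk.parse_duration("14:37:58")),
        ]
        rows = report_rows(results)
        assert rows[0]["sensitivity_pct"] == "n/a"
        assert rows[0]["specificity_pct"] == "100.00"
        assert rows[0]["false_neg"] == "n/a"
        assert rows[1]["specificity_pct"] == "99.99"
        assert rows[1]["fp_rate_per_hr"] == "0.27"
        fk.write_report(results, tmp_path / "r.csv")
        text = (tmp_path / "r.csv").read_text()
        assert "n/a" in text and "99.99" in text
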