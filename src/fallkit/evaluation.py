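"""Event-level scoring: sensitivity, specificity and false alarms per hour.

Detections are matched to annotated falls by greedy nearest-in-time
one-to-one matching within a tolerance (default ±20 s — self-reported fall
times are coarse). A matched detection is a true positive, an unmatched
detection a false positive, an unmatched annotation a false negative. True
negatives are counted per evaluated (non-suppressed) window that neither
overlaps an annotation ± tolerance nor was classified as a fall; this gives
the window-level specificity denominator a continuous stream needs.

The three performance measures:

    sensitivity = TP / (TP + FN)        (undefined when no falls occurred)
    specificity = TN / (TN + FP)        (undefined when TN + FP = 0)
    FP rate     = FP / monitored hours  (false alarms per hour)

Pooled rows sum counts and durations across subjects before recomputing the
ratios, so the pooled FP rate is (sum FP)/(sum hours), not a mean of rates.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .detector import LABEL_NON_FALL, DetectorConfig, DetectorState, detect_stream
from .io import AccelStream, DetectionEvent, FallAnnotation

logger = logging.getLogger("fallkit.evaluation")

DEFAULT_MATCH_TOL_S = 20.0


@dataclass
class EvalResult:
    """Detection performance of one subject (or a pooled total)."""

    subject: str
    true_pos: int
    false_neg: int
    false_pos: int
    true_neg: int
    monitored_hours: float

    @property
    def sensitivity(self) -> float | None:
        denom = self.true_pos + self.false_neg
        return self.true_pos / denom if denom > 0 else None

    @property
    def specificity(self) -> float | None:
        denom = self.true_neg + self.false_pos
        return self.true_neg / denom if denom > 0 else None

    @property
    def fp_rate(self) -> float:
        return fp_rate(self.false_pos, self.monitored_hours)

    @property
    def n_falls(self) -> int:
        return self.true_pos + self.false_neg


# ---------------------------------------------------------------------------
# Metric primitives
# ---------------------------------------------------------------------------

def sensitivity(tp: int, fn: int) -> float | None:
    """TP / (TP + FN): the fraction of true falls detected. None if no falls."""
    if tp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    return tp / (tp + fn) if tp + fn > 0 else None


def specificity(tn: int, fp: int) -> float | None:
    """TN / (TN + FP): the fraction of non-fall instances not alarmed."""
    if tn < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    return tn / (tn + fp) if tn + fp > 0 else None


def parse_duration(value: str | float) -> float:
    """Hours from an ``hh:mm:ss`` string (hours field unbounded) or a number."""
    if isinstance(value, (int, float)):
        return float(value)
    parts = [p.strip() for p in value.strip().split(":")]
    if len(parts) != 3:
        raise ValueError(f"expected hh:mm:ss, got {value!r}")
    h, m, s = (float(p) for p in parts)
    return h + m / 60.0 + s / 3600.0


def fp_rate(fp: int, monitored: str | float) -> float:
    """False alarms per hour: FP divided by the monitored duration in hours."""
    if fp < 0:
        raise ValueError("false-positive count must be non-negative")
    hours = parse_duration(monitored)
    if hours <= 0:
        raise ValueError(f"monitored duration must be positive, got {monitored!r}")
    return fp / hours


# ---------------------------------------------------------------------------
# Event matching
# ---------------------------------------------------------------------------

def match_events(
    detections: Sequence[DetectionEvent | float],
    annotations: Sequence[FallAnnotation | float],
    tol_s: float = DEFAULT_MATCH_TOL_S,
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """Greedy nearest-in-time one-to-one matching within ``±tol_s``.

    Candidate (detection, annotation) pairs within tolerance are consumed in
    order of ascending time gap; each event participates in at most one
    match. Ties on the gap are broken by earlier detection, then earlier
    annotation, keeping the result deterministic.

    Returns
    -------
    (TP, FP, FN, matches) with matches as (detection_index, annotation_index).
    """
    if tol_s < 0:
        raise ValueError(f"tolerance must be non-negative, got {tol_s}")
    det_t = [e.time if isinstance(e, DetectionEvent) else float(e) for e in detections]
    ann_t = [a.time if isinstance(a, FallAnnotation) else float(a) for a in annotations]

    candidates = sorted(
        (abs(d - a), i, j)
        for i, d in enumerate(det_t)
        for j, a in enumerate(ann_t)
        if abs(d - a) <= tol_s
    )
    det_used, ann_used = set(), set()
    matches: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i not in det_used and j not in ann_used:
            det_used.add(i)
            ann_used.add(j)
            matches.append((i, j))
    tp = len(matches)
    fp = len(det_t) - tp
    fn = len(ann_t) - tp
    return tp, fp, fn, sorted(matches)


# ---------------------------------------------------------------------------
# Full evaluation over streams
# ---------------------------------------------------------------------------

def _count_true_negatives(window_log, annotations, tol_s: float, window_s: float) -> int:
    """Evaluated non-suppressed, non-fall windows clear of any annotation ± tol."""
    ann_t = np.array([a.time for a in annotations], dtype=float)
    tn = 0
    for w in window_log:
        if w.label != LABEL_NON_FALL:
            continue
        if ann_t.size and np.any(
            (w.start_s <= ann_t + tol_s) & (w.start_s + window_s >= ann_t - tol_s)
        ):
            continue
        tn += 1
    return tn


def evaluate_subject(
    subject: str,
    stream: AccelStream,
    annotations: Sequence[FallAnnotation],
    model,
    cfg: DetectorConfig = DetectorConfig(),
    tol_s: float = DEFAULT_MATCH_TOL_S,
) -> tuple[EvalResult, list[DetectionEvent]]:
    """Detect falls on one subject's stream and score against annotations."""
    span = (stream.t0, stream.t0 + stream.duration_s)
    for a in annotations:
        if not span[0] <= a.time <= span[1]:
            raise ValueError(
                f"annotation at {a.time} s lies outside the stream span {span}"
            )
    events, window_log = detect_stream(stream, model, cfg)
    tp, fp, fn, _ = match_events(events, annotations, tol_s)
    tn = _count_true_negatives(window_log, annotations, tol_s, cfg.windowing.window_s)
    hours = stream.duration_s / 3600.0
    result = EvalResult(subject, tp, fn, fp, tn, hours)
    logger.info(
        "subject %s: %.2f h, falls=%d TP=%d FP=%d FN=%d TN=%d",
        subject, hours, len(annotations), tp, fp, fn, tn,
    )
    return result, events


def evaluate(
    subjects: Sequence[tuple[str, AccelStream, Sequence[FallAnnotation]]],
    model,
    cfg: DetectorConfig = DetectorConfig(),
    tol_s: float = DEFAULT_MATCH_TOL_S,
) -> list[EvalResult]:
    """Per-subject results plus a pooled ``Total`` row.

    The pooled row sums counts and durations before recomputing ratios, so
    its FP rate is (sum FP)/(sum hours).
    """
    results = [
        evaluate_subject(name, stream, anns, model, cfg, tol_s)[0]
        for name, stream, anns in subjects
    ]
    pooled = EvalResult(
        "Total",
        sum(r.true_pos for r in results),
        sum(r.false_neg for r in results),
        sum(r.false_pos for r in results),
        sum(r.true_neg for r in results),
        sum(r.monitored_hours for r in results),
    )
    return results + [pooled]


# ---------------------------------------------------------------------------
# Report formatting
# ---------------------------------------------------------------------------

def format_hours(hours: float) -> str:
    """Render hours as hh:mm:ss (hours field unbounded)."""
    total = int(round(hours * 3600))
    h, rem = divmod(total, 3600)
    m, s = divmod(rem, 60)
    return f"{h}:{m:02d}:{s:02d}"


def _pct(x: float | None) -> str:
    return "n/a" if x is None else f"{100 * x:.2f}"


def report_rows(results: Sequence[EvalResult]) -> list[dict]:
    """Table rows: subject, duration, falls, sens %, spec %, FN, FP, FP/hr."""
    return [
        {
            "subject": r.subject,
            "duration": format_hours(r.monitored_hours),
            "falls": r.n_falls,
            "sensitivity_pct": _pct(r.sensitivity),
            "specificity_pct": _pct(r.specificity),
            "false_neg": "n/a" if r.sensitivity is None else r.false_neg,
            "false_pos": r.false_pos,
            "fp_rate_per_hr": f"{r.fp_rate:.2f}",
        }
        for r in results
    ]


def write_report(results: Sequence[EvalResult], path: str | Path) -> None:
    rows = report_rows(results)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
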