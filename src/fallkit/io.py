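"""Reading and writing accelerometer streams, annotations, events and models.

All downstream modules consume the container types defined here. The on-disk
dialects are deliberately minimal and text-based:

* stream CSV — header ``t,ax,ay,az``; time in seconds, acceleration in g
  (gravity included, so a resting upright sensor reads magnitude ~1 g);
* annotation CSV — header ``time,label``;
* detection CSV — header ``time``;
* model archive — a single joblib file wrapping the fitted model with a
  format tag (see :func:`save_model`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

logger = logging.getLogger("fallkit.io")

MODEL_FORMAT = "fallkit-model/1"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AccelStream:
    """A uniformly sampled tri-axial acceleration series.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz; must be positive.
    samples : ndarray of shape (n, 3)
        Acceleration in g along the sensor x, y, z axes, gravity included.
        Every component must lie within ``[-sensor_range, +sensor_range]``.
    t0 : float
        Epoch of the first sample, in seconds.
    subject_id : str
        Opaque label identifying the wearer.
    sensor_range : float
        Saturation limit of the device in g (e.g. 2.0 or 6.0).
    """

    sample_rate: float
    samples: np.ndarray
    t0: float = 0.0
    subject_id: str = ""
    sensor_range: float = 6.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1, 3)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.sensor_range <= 0:
            raise ValueError(f"sensor_range must be positive, got {self.sensor_range}")
        if self.samples.size and np.max(np.abs(self.samples)) > self.sensor_range + 1e-9:
            raise ValueError(
                "samples exceed sensor_range "
                f"±{self.sensor_range} g; clip before constructing the stream"
            )

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        """Total covered time: n samples at rate f span n/f seconds."""
        return len(self) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Timestamp of sample i is ``t0 + i / sample_rate``."""
        return self.t0 + np.arange(len(self)) / self.sample_rate


@dataclass(frozen=True, order=True)
class FallAnnotation:
    """Ground-truth fall occurrence: the instant of impact on the timeline."""

    time: float
    label: str = "fall"


@dataclass(frozen=True, order=True)
class DetectionEvent:
    """A predicted fall, stamped with the start of the triggering window."""

    time: float


# ---------------------------------------------------------------------------
# Stream I/O
# ---------------------------------------------------------------------------

def clip_to_range(samples: np.ndarray, sensor_range: float) -> np.ndarray:
    """Clip components to ``[-sensor_range, +sensor_range]`` (idempotent)."""
    return np.clip(samples, -sensor_range, sensor_range)


def read_stream(
    path: str | Path,
    sample_rate: float,
    sensor_range: float = 6.0,
    subject_id: str = "",
) -> AccelStream:
    """Read a delimited-text acceleration file into an :class:`AccelStream`.

    The file must have 3 numeric columns (x, y, z in g) or 4 (a leading time
    column, which is validated against uniform sampling but not trusted).
    Values outside ``sensor_range`` are clipped with a warning, mirroring
    physical sensor saturation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stream file not found: {path}")
    try:
        df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        return AccelStream(sample_rate, np.empty((0, 3)), 0.0, subject_id, sensor_range)

    # Tolerate our own header line (or any non-numeric first row).
    first = df.iloc[0]
    if any(isinstance(v, str) and _not_numeric(v) for v in first):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 or 4 columns, found {df.shape[1]}")

    arr = np.empty((len(df), df.shape[1]), dtype=float)
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            arr[i] = [float(v) for v in row]
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric value in data row {i + 1}") from exc

    t0 = 0.0
    if arr.shape[1] >= 4:
        tcol, arr = arr[:, 0], arr[:, 1:4]
        if len(tcol):
            t0 = float(tcol[0])
            expected = t0 + np.arange(len(tcol)) / sample_rate
            if np.max(np.abs(tcol - expected)) > 0.5 / sample_rate:
                logger.warning(
                    "%s: time column deviates from uniform %g Hz sampling; "
                    "timestamps are derived from sample index instead", path, sample_rate
                )
    else:
        arr = arr[:, :3]

    if arr.size and np.max(np.abs(arr)) > sensor_range:
        logger.warning("%s: values outside ±%g g clipped (sensor saturation)", path, sensor_range)
        arr = clip_to_range(arr, sensor_range)
    return AccelStream(sample_rate, arr, t0, subject_id, sensor_range)


def _not_numeric(value: str) -> bool:
    try:
        float(value)
        return False
    except ValueError:
        return True


def write_stream(stream: AccelStream, path: str | Path) -> None:
    """Write a stream in the ``t,ax,ay,az`` CSV dialect."""
    path = Path(path)
    try:
        df = pd.DataFrame(stream.samples, columns=["ax", "ay", "az"])
        df.insert(0, "t", stream.times)
        df.to_csv(path, index=False, float_format="%.9f")
    except OSError as exc:
        raise OSError(f"failed to write stream to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Annotation / event I/O
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> list[FallAnnotation]:
    """Read a ``time,label`` CSV into time-sorted :class:`FallAnnotation` list."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    df = pd.read_csv(path)
    if len(df) == 0:
        return []
    out = [FallAnnotation(float(t), str(lab)) for t, lab in zip(df["time"], df["label"])]
    return sorted(out)


def write_annotations(annotations: Sequence[FallAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {"time": [a.time for a in annotations], "label": [a.label for a in annotations]}
    ).to_csv(path, index=False)


def read_events(path: str | Path) -> list[DetectionEvent]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"event file not found: {path}")
    df = pd.read_csv(path)
    return sorted(DetectionEvent(float(t)) for t in df["time"]) if len(df) else []


def write_events(events: Sequence[DetectionEvent], path: str | Path) -> None:
    try:
        pd.DataFrame({"time": [e.time for e in events]}).to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"failed to write events to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Persist a trained model as a single self-describing archive.

    The archive bundles the fitted kernel machine, the chosen (C, gamma),
    the normalization bounds and the windowing config — everything needed
    to classify a fresh stream.
    """
    joblib.dump({"format": MODEL_FORMAT, "model": model}, path)


def load_model(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model archive not found: {path}")
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path}: not a recognized model archive")
    return payload["model"]
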