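"""Streaming fall detection with a post-alarm refractory period.

The trained model is slid over the continuous stream: each complete 2.5 s
window is featurized, normalized with the model's frozen bounds, and
classified in time order. A fall-labeled window raises a DetectionEvent at
its start time and suppresses every window whose start falls within the next
``refractory_s`` seconds (default 30 s), so one physical fall cannot raise a
burst of alarms. Suppressed windows are logged as suppressed, not evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import FALL, TrainedModel
from .features import WindowingConfig, apply_normalizer, feature_matrix
from .io import AccelStream, DetectionEvent

LABEL_FALL = "fall"
LABEL_NON_FALL = "non_fall"
LABEL_SUPPRESSED = "suppressed"


@dataclass(frozen=True)
class DetectorConfig:
    refractory_s: float = 30.0
    windowing: WindowingConfig = field(default_factory=WindowingConfig)

    def __post_init__(self) -> None:
        if self.refractory_s < 0:
            raise ValueError(f"refractory_s must be >= 0, got {self.refractory_s}")


@dataclass
class WindowDecision:
    """Audit record of one window: its start and how it was handled."""

    start_s: float
    label: str  # fall | non_fall | suppressed


@dataclass
class DetectorState:
    """Carryable refractory state, so a stream may be processed in chunks."""

    last_event_s: float | None = None

    def suppressed(self, start_s: float, refractory_s: float) -> bool:
        return (
            self.last_event_s is not None
            and 0 <= start_s - self.last_event_s < refractory_s
            and start_s > self.last_event_s
        )


def detect_stream(
    stream: AccelStream,
    model: TrainedModel,
    cfg: DetectorConfig = DetectorConfig(),
    state: DetectorState | None = None,
) -> tuple[list[DetectionEvent], list[WindowDecision]]:
    """Run the classifier over a stream and emit refractory-gated fall events.

    Deterministic for a fixed model and stream. Pass a shared
    :class:`DetectorState` to process a long recording in window-aligned
    chunks with identical output to a single pass.

    Returns
    -------
    events : list of DetectionEvent, ascending, consecutive gaps >= refractory_s
    window_log : one WindowDecision per window, in time order
    """
    if cfg.windowing != model.windowing:
        raise ValueError(
            f"detector windowing {cfg.windowing} does not match the model's "
            f"training windowing {model.windowing}"
        )
    state = state if state is not None else DetectorState()
    starts, X_raw = feature_matrix(stream, cfg.windowing)
    if len(starts) == 0:
        return [], []
    # Batch classification is safe: suppression only gates which fall labels
    # become events, it does not alter any window's features.
    labels = model.predict(apply_normalizer(model.normalizer, X_raw))

    events: list[DetectionEvent] = []
    log: list[WindowDecision] = []
    for start_s, label in zip(starts, labels):
        if state.suppressed(start_s, cfg.refractory_s):
            log.append(WindowDecision(float(start_s), LABEL_SUPPRESSED))
            continue
        if label == FALL:
            events.append(DetectionEvent(float(start_s)))
            state.last_event_s = float(start_s)
            log.append(WindowDecision(float(start_s), LABEL_FALL))
        else:
            log.append(WindowDecision(float(start_s), LABEL_NON_FALL))
    return events, log
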