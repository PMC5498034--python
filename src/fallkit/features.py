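"""Windowed feature extraction and [0, 1] normalization.

Each analysis window of 2.5 s is summarized by six numbers: the mean and the
population variance of each of the three acceleration axes, in the fixed
order (mean_x, mean_y, mean_z, var_x, var_y, var_z). Consecutive windows
overlap by 1.5 s, i.e. the hop is 1.0 s at the defaults. Features are min-max
normalized with bounds fitted on the training matrix and applied frozen (with
clipping) at test time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AccelStream

FEATURE_NAMES = ("mean_x", "mean_y", "mean_z", "var_x", "var_y", "var_z")
N_FEATURES = 6


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window geometry: window length and overlap, in seconds."""

    window_s: float = 2.5
    overlap_s: float = 1.5

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_s < self.window_s:
            raise ValueError(
                f"need 0 <= overlap_s < window_s, got overlap={self.overlap_s}, "
                f"window={self.window_s}"
            )

    @property
    def hop_s(self) -> float:
        return self.window_s - self.overlap_s

    def window_samples(self, sample_rate: float) -> int:
        """Window length in samples, aligned to the sampling grid."""
        return int(round(self.window_s * sample_rate))

    def hop_samples(self, sample_rate: float) -> int:
        n = int(round(self.hop_s * sample_rate))
        if n < 1:
            raise ValueError(f"hop of {self.hop_s} s is below one sample at {sample_rate} Hz")
        return n


@dataclass(frozen=True)
class WindowFeatures:
    """The 6-dimensional feature vector of one window."""

    start_s: float
    values: np.ndarray  # (mean_x, mean_y, mean_z, var_x, var_y, var_z)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} feature values, got {self.values.shape}")
        if np.any(self.values[3:] < 0):
            raise ValueError("variances must be non-negative")


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature (min, max) bounds fitted on the training matrix."""

    minima: np.ndarray
    maxima: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "minima", np.asarray(self.minima, dtype=float))
        object.__setattr__(self, "maxima", np.asarray(self.maxima, dtype=float))
        if self.minima.shape != self.maxima.shape:
            raise ValueError("minima and maxima must have the same shape")
        if np.any(self.maxima < self.minima):
            raise ValueError("max must be >= min for every feature")


def slide_windows(stream: AccelStream, cfg: WindowingConfig) -> list[tuple[float, np.ndarray]]:
    """Enumerate complete sliding windows of a stream.

    Window k starts at ``t0 + k * hop_s``; only windows fully contained in
    the stream are emitted, so a stream shorter than one window yields none.

    Returns
    -------
    list of (start_s, samples) with samples of shape (window_samples, 3).
    """
    win = cfg.window_samples(stream.sample_rate)
    hop = cfg.hop_samples(stream.sample_rate)
    n = len(stream)
    if n < win:
        return []
    out = []
    for k in range((n - win) // hop + 1):
        i = k * hop
        out.append((stream.t0 + i / stream.sample_rate, stream.samples[i : i + win]))
    return out


def window_features(samples: np.ndarray, start_s: float = 0.0) -> WindowFeatures:
    """Per-axis mean and population variance of one window.

    Population variance (divide by n, not n-1) is used; with >= 100 samples
    per window the distinction is immaterial but a fixed definition keeps
    results reproducible.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot compute features of an empty window")
    samples = samples.reshape(-1, 3)
    means = samples.mean(axis=0)
    variances = samples.var(axis=0)  # ddof=0 -> population variance
    return WindowFeatures(start_s, np.concatenate([means, variances]))


def feature_matrix(stream: AccelStream, cfg: WindowingConfig) -> tuple[np.ndarray, np.ndarray]:
    """Featurize every window of a stream.

    Vectorized equivalent of calling :func:`window_features` per window;
    returns ``(starts, X)`` with X of shape (n_windows, 6).
    """
    win = cfg.window_samples(stream.sample_rate)
    hop = cfg.hop_samples(stream.sample_rate)
    n = len(stream)
    if n < win:
        return np.empty(0), np.empty((0, N_FEATURES))
    n_win = (n - win) // hop + 1
    starts = stream.t0 + np.arange(n_win) * hop / stream.sample_rate
    # cumulative sums give O(n) window means/variances
    c1 = np.vstack([np.zeros(3), np.cumsum(stream.samples, axis=0)])
    c2 = np.vstack([np.zeros(3), np.cumsum(stream.samples**2, axis=0)])
    idx = np.arange(n_win) * hop
    s1 = c1[idx + win] - c1[idx]
    s2 = c2[idx + win] - c2[idx]
    means = s1 / win
    variances = np.maximum(s2 / win - means**2, 0.0)
    return starts, np.hstack([means, variances])


def fit_normalizer(X: np.ndarray) -> NormalizationParams:
    """Fit per-feature min/max bounds on a training feature matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need a non-empty 2-D feature matrix")
    return NormalizationParams(X.min(axis=0), X.max(axis=0))


def apply_normalizer(params: NormalizationParams, X: np.ndarray) -> np.ndarray:
    """Map features to [0, 1] with the fitted bounds.

    ``(x - min) / (max - min)`` per feature; values outside the training
    range are clipped to [0, 1], and a degenerate feature (max == min)
    maps to 0 to avoid division by zero.
    """
    X = np.asarray(X, dtype=float)
    span = params.maxima - params.minima
    safe = np.where(span > 0, span, 1.0)
    out = (X - params.minima) / safe
    out = np.where(span > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)
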