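"""Shared fixtures: simulated protocol datasets and trained models.

The expensive artifacts (the full laboratory protocol and the model trained
on it with the complete hyperparameter grid) are session-scoped so the whole
suite trains them once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import fallkit as fk

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_trials():
    """The full simulated laboratory protocol: 210 fall + 390 non-fall trials."""
    return fk.generate_protocol_dataset(fk.ProtocolSpec())


@pytest.fixture(scope="session")
def default_model(default_trials):
    """Model trained with the complete 21 x 19 grid on the default protocol."""
    model, report = fk.train_pipeline(default_trials)
    model.report = report
    return model


@pytest.fixture(scope="session")
def quick_model():
    """A cheap but genuine model (small protocol, reduced grid) for unit tests."""
    trials = fk.generate_protocol_dataset(
        fk.ProtocolSpec(n_participants=2, trials_per_category=2, seed=5)
    )
    grid = fk.SVMGrid(C_exponents=(0, 5), gamma_exponents=(-3, 0, 3), folds=4)
    model, _ = fk.train_pipeline(trials, grid)
    return model


class ThresholdModel:
    """Deterministic stand-in classifier for detector/evaluation unit tests.

    Labels a window as a fall when its raw mean_z exceeds 0.5. The identity
    normalizer keeps raw and normalized features equal on [0, 1].
    """

    def __init__(self, windowing: fk.WindowingConfig | None = None):
        self.windowing = windowing or fk.WindowingConfig()
        self.normalizer = fk.NormalizationParams(np.zeros(6), np.ones(6))

    def predict(self, X):
        return (np.asarray(X)[:, 2] > 0.5).astype(int)


@pytest.fixture
def threshold_model():
    return ThresholdModel()


def steps_stream(pattern: str, seconds_per_step: float = 1.0, rate: float = 100.0):
    """A stream whose z axis follows a 0/1 pattern, one char per step.

    With the default 2.5 s window and 1 s hop, a window is fall-labeled by
    :class:`ThresholdModel` when the majority of its span covers '1' steps.
    """
    z = np.repeat([float(c) for c in pattern], int(seconds_per_step * rate))
    samples = np.zeros((len(z), 3))
    samples[:, 2] = z
    return fk.AccelStream(rate, samples)
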