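"""Synthetic tri-axial accelerometer signals: falls, near-falls and ADLs.

Stands in for non-public recordings in two forms:

* a laboratory-protocol trial set — 7 fall types, 5 near-falls and 8
  activities of daily living (ADLs), 3 trials per category for each of 10
  participants, i.e. 210 fall and 390 non-fall trials at the defaults;
* long continuous daily-activity streams with sparse embedded falls, for
  sensors saturating at ±6 g or ±2 g.

The fall signature follows the canonical accelerometric morphology: a
free-fall descent (vertical magnitude dipping toward ~0.4 g), a sharp impact
spike (3–5 g, 50–150 ms), then still lying with the gravity vector rotated
off the vertical axis. Near-falls share the dip and a moderate spike
(2–3.5 g) but recover to upright activity — no lying phase — which makes
them the key false-alarm source a trained model must reject. ADLs are
periodic (walking, ~2 Hz) or transient (postural transitions, <= 1.8 g)
and never combine an impact spike with a lying phase.

All generators are pure functions of (parameters, seed): a rerun with the
same seed is bit-identical. Units are g with gravity included; while upright
the sensor z axis carries gravity, so a resting stream reads (0, 0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from pathlib import Path

from .io import AccelStream, FallAnnotation, clip_to_range, read_stream, write_stream

DEFAULT_SAMPLE_RATE = 100.0
DEFAULT_SENSOR_RANGE = 6.0
DEFAULT_NOISE_SD = 0.05  # additive white Gaussian, in g

ADL_KINDS = (
    "walking",
    "standing",
    "sitting",
    "sit_to_stand",
    "stand_to_sit",
    "lie_down",
    "stand_up",
    "reaching",
)

NEAR_FALL_KINDS = (
    "trip_recovery",
    "slip_recovery",
    "stumble_recovery",
    "misstep_recovery",
    "sway_recovery",
)

# Fall-category presets differ only by parameter ranges (impact severity,
# descent speed, resting orientation) — label structure, not biomechanics.
FALL_KINDS = (
    "incorrect_weight_shift",
    "trip",
    "hit_bump",
    "collapse",
    "slip",
    "forward_fall",
    "backward_fall",
)

_FALL_PRESETS: dict[str, dict] = {
    "incorrect_weight_shift": {"impact_peak_range": (3.0, 4.0)},
    "trip": {"impact_peak_range": (3.5, 5.0), "lying_axis": 0},
    "hit_bump": {"impact_peak_range": (3.5, 5.0), "lying_axis": 1},
    "collapse": {"impact_peak_range": (3.0, 4.0), "descent_range": (0.4, 0.5)},
    "slip": {"impact_peak_range": (3.5, 5.0), "descent_range": (0.3, 0.4)},
    "forward_fall": {"lying_axis": 0, "lying_sign": 1.0},
    "backward_fall": {"lying_axis": 0, "lying_sign": -1.0},
}


@dataclass(frozen=True)
class FallSignatureParams:
    """Amplitude/duration ranges of the synthetic fall signature (units g, s)."""

    pre_activity_s: float = 4.0
    descent_range: tuple[float, float] = (0.3, 0.5)
    descent_dip_g: float = 0.4
    impact_peak_range: tuple[float, float] = (3.0, 5.0)
    impact_duration_range: tuple[float, float] = (0.05, 0.15)
    lying_s: float = 20.0
    lying_axis: int = 0       # axis receiving gravity after the 90° rotation
    lying_sign: float = 1.0
    noise_sd_g: float = DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        for name in ("pre_activity_s", "lying_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lying_axis not in (0, 1):
            raise ValueError("lying_axis must be 0 (x) or 1 (y)")


@dataclass(frozen=True)
class ProtocolSpec:
    """Shape of the simulated laboratory protocol."""

    n_participants: int = 10
    trials_per_category: int = 3
    fall_categories: int = 7
    near_fall_categories: int = 5
    adl_categories: int = 8
    seed: int = 0
    sample_rate: float = DEFAULT_SAMPLE_RATE
    sensor_range: float = DEFAULT_SENSOR_RANGE

    def __post_init__(self) -> None:
        for name in ("n_participants", "trials_per_category", "fall_categories",
                     "near_fall_categories", "adl_categories"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class Trial:
    """One labeled laboratory trial."""

    participant: int
    category: str
    label: str  # "fall" | "non_fall"
    trial_index: int
    stream: AccelStream
    annotation: FallAnnotation | None = None


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    return rng.normal(0.0, sd, size=(n, 3))


def _upright(n: int, rng: np.random.Generator, sd: float, sway: float = 0.03,
             rate: float = DEFAULT_SAMPLE_RATE) -> np.ndarray:
    """Quiet standing: gravity on z plus slow postural sway."""
    t = np.arange(n) / rate
    seg = np.zeros((n, 3))
    seg[:, 2] = 1.0 + sway * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    return seg + _noise(rng, n, sd)


def _walking(n: int, rng: np.random.Generator, sd: float,
             rate: float = DEFAULT_SAMPLE_RATE,
             freq_range=(1.8, 2.2), amp_range=(0.3, 0.55)) -> np.ndarray:
    """Gait oscillation at step frequency ~2 Hz, vertical amplitude <= 0.6 g."""
    t = np.arange(n) / rate
    f = rng.uniform(*freq_range)
    a = rng.uniform(*amp_range)
    phase = rng.uniform(0, 2 * np.pi)
    seg = np.zeros((n, 3))
    seg[:, 2] = 1.0 + a * np.sin(2 * np.pi * f * t + phase)
    seg[:, 0] = 0.25 * a * np.sin(2 * np.pi * f * t + phase + rng.uniform(0, np.pi))
    seg[:, 1] = 0.2 * a * np.sin(np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return seg + _noise(rng, n, sd)


def _lying(n: int, rng: np.random.Generator, axis: int, sign: float,
           sd: float = 0.02) -> np.ndarray:
    """Still lying: gravity rotated 90° onto a horizontal axis, variance ~0."""
    seg = np.zeros((n, 3))
    seg[:, axis] = sign
    return seg + _noise(rng, n, sd)


def _bump(n: int, peak: float, rate: float) -> np.ndarray:
    """A smooth symmetric vertical bump (postural transition), peak in g above 1."""
    t = np.linspace(-1, 1, n)
    return peak * np.exp(-(t / 0.4) ** 2)


# ---------------------------------------------------------------------------
# Segment generators
# ---------------------------------------------------------------------------

def simulate_fall(
    params: FallSignatureParams = FallSignatureParams(),
    rng: np.random.Generator | int = 0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    sensor_range: float = DEFAULT_SENSOR_RANGE,
) -> tuple[AccelStream, FallAnnotation]:
    """One fall trial: pre-activity, descent, impact, still lying.

    The annotation marks the impact peak. During lying the resultant
    magnitude stays within 1 ± 0.1 g and per-axis variance is far below the
    descent+impact phase.
    """
    rng = _rng(rng)
    n_pre = int(round(params.pre_activity_s * sample_rate))
    n_desc = int(round(rng.uniform(*params.descent_range) * sample_rate))
    n_imp = max(int(round(rng.uniform(*params.impact_duration_range) * sample_rate)), 3)
    n_lie = int(round(params.lying_s * sample_rate))
    sd = params.noise_sd_g

    pre = _upright(n_pre, rng, sd, rate=sample_rate)

    # descent: vertical magnitude ramps from ~1 g toward free-fall (~0.4 g)
    dip = rng.uniform(params.descent_dip_g - 0.05, params.descent_dip_g + 0.05)
    desc = np.zeros((n_desc, 3))
    desc[:, 2] = np.linspace(1.0, dip, n_desc)
    desc += _noise(rng, n_desc, sd)

    peak = rng.uniform(*params.impact_peak_range)
    imp = np.zeros((n_imp, 3))
    shape = np.sin(np.linspace(0, np.pi, n_imp))  # half-sine spike
    imp[:, 2] = peak * shape
    imp[:, params.lying_axis] = params.lying_sign * 0.5 * peak * shape
    imp += _noise(rng, n_imp, sd)

    lie = _lying(n_lie, rng, params.lying_axis, params.lying_sign)

    samples = clip_to_range(np.vstack([pre, desc, imp, lie]), sensor_range)
    stream = AccelStream(sample_rate, samples, sensor_range=sensor_range)
    impact_time = (n_pre + n_desc + n_imp // 2) / sample_rate
    return stream, FallAnnotation(impact_time)


def simulate_adl(
    kind: str,
    rng: np.random.Generator | int = 0,
    duration_s: float = 12.0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    sensor_range: float = DEFAULT_SENSOR_RANGE,
    noise_sd_g: float = DEFAULT_NOISE_SD,
) -> AccelStream:
    """One activity-of-daily-living segment of the requested kind.

    Periodic (walking: ~2 Hz vertical oscillation, amplitude <= 0.6 g) or
    transient (postural transitions: one smooth <= 1.8 g bump) — never the
    impact-spike-plus-lying conjunction of a fall.
    """
    if kind not in ADL_KINDS:
        raise ValueError(f"unknown ADL kind {kind!r}; known: {ADL_KINDS}")
    rng = _rng(rng)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    sd = noise_sd_g

    if kind == "walking":
        seg = _walking(n, rng, sd, sample_rate)
    elif kind == "standing":
        seg = _upright(n, rng, sd, rate=sample_rate)
    elif kind == "sitting":
        seg = np.zeros((n, 3))
        tilt = rng.uniform(0.1, 0.3)
        seg[:, 0] = tilt
        seg[:, 2] = np.sqrt(1 - tilt**2)
        seg += _noise(rng, n, sd)
    elif kind in ("sit_to_stand", "stand_to_sit"):
        seg = _upright(n, rng, sd, sway=0.02, rate=sample_rate)
        width = int(round(rng.uniform(0.8, 1.2) * sample_rate))
        peak = rng.uniform(0.2, 0.6)  # keeps magnitude <= ~1.8 g
        center = n // 2
        lo, hi = max(center - width // 2, 0), min(center + width // 2, n)
        bump = _bump(hi - lo, peak, sample_rate)
        seg[lo:hi, 2] += bump if kind == "sit_to_stand" else -0.6 * bump
    elif kind in ("lie_down", "stand_up"):
        # smooth 90° rotation of gravity between z and a horizontal axis:
        # orientation change without an impact spike, and still lying
        # without an impact, are the two patterns a fall detector must NOT
        # alarm on. lie_down trials rotate early so the trial midpoint is
        # quiet lying; stand_up trials center the rotation at the midpoint.
        # The unhurried 2.5-4 s rotation is a deliberate, realistic
        # contrast with the sub-second fall descent+impact.
        axis = int(rng.integers(0, 2))
        n_trans = min(int(round(rng.uniform(2.5, 4.0) * sample_rate)), n)
        if kind == "lie_down":
            start = min(int(round(rng.uniform(0.5, 1.5) * sample_rate)),
                        max(n - n_trans, 0))
        else:
            jitter = int(round(rng.uniform(-0.5, 0.5) * sample_rate))
            start = min(max(n // 2 - n_trans // 2 + jitter, 0), max(n - n_trans, 0))
        ramp = np.linspace(0, np.pi / 2, n_trans)
        theta = np.empty(n)
        if kind == "lie_down":
            theta[:start] = 0.0
            theta[start : start + n_trans] = ramp
            theta[start + n_trans :] = np.pi / 2
        else:
            theta[:start] = np.pi / 2
            theta[start : start + n_trans] = ramp[::-1]
            theta[start + n_trans :] = 0.0
        seg = np.zeros((n, 3))
        seg[:, 2] = np.cos(theta)
        seg[:, axis] = np.sin(theta)
        seg += _noise(rng, n, 0.03)
    elif kind == "reaching":
        seg = np.zeros((n, 3))
        f = rng.uniform(0.4, 0.7)
        a = rng.uniform(0.15, 0.3)
        seg[:, 2] = 1.0 + a * np.sin(2 * np.pi * f * t)
        seg[:, 0] = a * np.sin(2 * np.pi * f * t + rng.uniform(0, np.pi))
        seg += _noise(rng, n, sd)

    return AccelStream(sample_rate, clip_to_range(seg, sensor_range),
                       sensor_range=sensor_range)


def simulate_near_fall(
    rng: np.random.Generator | int = 0,
    duration_s: float = 10.0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    sensor_range: float = DEFAULT_SENSOR_RANGE,
    spike_range: tuple[float, float] = (2.0, 3.5),
    noise_sd_g: float = DEFAULT_NOISE_SD,
) -> AccelStream:
    """An imbalance episode with recovery: dip and moderate spike, no lying.

    The subject resumes upright activity immediately, so the final seconds
    show mean resultant magnitude ~1 g with nonzero gait variance.
    """
    rng = _rng(rng)
    n = int(round(duration_s * sample_rate))
    n_dip = int(round(rng.uniform(0.2, 0.3) * sample_rate))
    n_spk = max(int(round(rng.uniform(0.05, 0.1) * sample_rate)), 3)
    mid = n // 2
    n_before = mid - n_dip - n_spk // 2
    n_after = n - n_before - n_dip - n_spk
    sd = noise_sd_g

    before = _walking(n_before, rng, sd, sample_rate, amp_range=(0.2, 0.4))
    dip = np.zeros((n_dip, 3))
    dip[:, 2] = np.linspace(1.0, rng.uniform(0.5, 0.7), n_dip)
    dip += _noise(rng, n_dip, sd)
    peak = rng.uniform(*spike_range)
    spike = np.zeros((n_spk, 3))
    spike[:, 2] = peak * np.sin(np.linspace(0, np.pi, n_spk))
    spike[:, 0] = 0.3 * peak * np.sin(np.linspace(0, np.pi, n_spk))
    spike += _noise(rng, n_spk, sd)
    after = _walking(n_after, rng, sd, sample_rate, amp_range=(0.2, 0.4))

    seg = clip_to_range(np.vstack([before, dip, spike, after]), sensor_range)
    return AccelStream(sample_rate, seg, sensor_range=sensor_range)


# ---------------------------------------------------------------------------
# Protocol dataset and continuous streams
# ---------------------------------------------------------------------------

def _category_names(prefix_list: tuple[str, ...], count: int) -> list[str]:
    """First `count` names, cycling with numeric suffixes if count exceeds presets."""
    names = []
    for i in range(count):
        base = prefix_list[i % len(prefix_list)]
        names.append(base if i < len(prefix_list) else f"{base}_{i // len(prefix_list) + 1}")
    return names


def generate_protocol_dataset(spec: ProtocolSpec = ProtocolSpec()) -> list[Trial]:
    """The simulated laboratory protocol as a labeled trial collection.

    Every participant performs ``trials_per_category`` trials of every fall,
    near-fall and ADL category; fall categories are labeled ``fall``, the
    rest ``non_fall``. At the defaults this yields 10 x 3 x 7 = 210 fall and
    10 x 3 x (5 + 8) = 390 non-fall trials. Per-trial randomness is seeded
    from (spec.seed, participant, category index, trial index), so the
    collection is rerun-identical and order-independent.
    """
    falls = _category_names(FALL_KINDS, spec.fall_categories)
    nears = _category_names(NEAR_FALL_KINDS, spec.near_fall_categories)
    adls = _category_names(ADL_KINDS, spec.adl_categories)

    trials: list[Trial] = []
    categories = [(c, "fall") for c in falls] + \
                 [(c, "near_fall") for c in nears] + \
                 [(c, "adl") for c in adls]
    for p in range(spec.n_participants):
        for ci, (cat, group) in enumerate(categories):
            for t in range(spec.trials_per_category):
                rng = np.random.default_rng([spec.seed % (2**31), p, ci, t])
                if group == "fall":
                    preset = _FALL_PRESETS.get(cat.rsplit("_", 1)[0], {})
                    preset = _FALL_PRESETS.get(cat, preset)
                    params = replace(FallSignatureParams(), **preset)
                    stream, ann = simulate_fall(params, rng, spec.sample_rate,
                                                spec.sensor_range)
                    trials.append(Trial(p, cat, "fall", t, stream, ann))
                elif group == "near_fall":
                    stream = simulate_near_fall(rng, sample_rate=spec.sample_rate,
                                                sensor_range=spec.sensor_range)
                    trials.append(Trial(p, cat, "non_fall", t, stream))
                else:
                    base = cat if cat in ADL_KINDS else cat.rsplit("_", 1)[0]
                    stream = simulate_adl(base, rng, sample_rate=spec.sample_rate,
                                          sensor_range=spec.sensor_range)
                    trials.append(Trial(p, cat, "non_fall", t, stream))
    return trials


def _lying_bout(rng: np.random.Generator, sample_rate: float,
                sd: float = DEFAULT_NOISE_SD) -> np.ndarray:
    """A complete lying episode for continuous streams.

    Upright -> slow rotation down -> still lying -> slow rotation up ->
    upright, all on one consistent horizontal axis, so the bout starts and
    ends upright and background concatenation never splices two different
    resting orientations together.
    """
    axis = int(rng.integers(0, 2))
    n_up1 = int(round(rng.uniform(2.0, 5.0) * sample_rate))
    n_down = int(round(rng.uniform(2.5, 4.0) * sample_rate))
    n_lie = int(round(rng.uniform(8.0, 25.0) * sample_rate))
    n_rise = int(round(rng.uniform(2.5, 4.0) * sample_rate))
    n_up2 = int(round(rng.uniform(2.0, 5.0) * sample_rate))

    theta = np.concatenate([
        np.zeros(n_up1),
        np.linspace(0, np.pi / 2, n_down),
        np.full(n_lie, np.pi / 2),
        np.linspace(np.pi / 2, 0, n_rise),
        np.zeros(n_up2),
    ])
    seg = np.zeros((len(theta), 3))
    seg[:, 2] = np.cos(theta)
    seg[:, axis] = np.sin(theta)
    noise_sd = np.where(theta > np.pi / 2 - 0.05, 0.02, 0.04)  # stiller while lying
    seg += rng.normal(0.0, 1.0, size=seg.shape) * noise_sd[:, None]
    return seg


DEFAULT_ADL_MIX: dict[str, float] = {
    "walking": 0.40,
    "standing": 0.15,
    "sitting": 0.15,
    "reaching": 0.10,
    "sit_to_stand": 0.07,
    "stand_to_sit": 0.07,
    "lie_down": 0.03,
    "stand_up": 0.03,
}

_FALL_LEAD_S = 1.0  # descent starts this long after signature insertion point


def generate_stream(
    duration_s: float,
    fall_times: list[float] | tuple[float, ...] = (),
    rng: np.random.Generator | int = 0,
    adl_mix: dict[str, float] | None = None,
    sensor_range: float = DEFAULT_SENSOR_RANGE,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    fall_params: FallSignatureParams | None = None,
    subject_id: str = "",
) -> tuple[AccelStream, list[FallAnnotation]]:
    """A continuous daily-activity stream with falls embedded at given times.

    The background concatenates ADL segments drawn from ``adl_mix``; at each
    requested time a fall signature (short pre-activity, descent, impact,
    lying) overwrites the background with its impact at that instant. Values
    are clipped to ``sensor_range``, so a 5 g impact recorded on a ±2 g
    device saturates at exactly 2 g.

    Requires fall times within the stream (with room for the lying phase)
    and pairwise gaps > 60 s; overlapping placements are an error.
    """
    rng = _rng(rng)
    if fall_params is None:
        fall_params = replace(FallSignatureParams(), pre_activity_s=_FALL_LEAD_S)
    mix = dict(DEFAULT_ADL_MIX if adl_mix is None else adl_mix)
    kinds = list(mix)
    weights = np.array([mix[k] for k in kinds], dtype=float)
    weights /= weights.sum()

    n_total = int(round(duration_s * sample_rate))
    fall_times = sorted(float(t) for t in fall_times)
    for a, b in zip(fall_times, fall_times[1:]):
        if b - a <= 60.0:
            raise ValueError(f"fall times {a} s and {b} s are within 60 s of each other")

    # background of concatenated ADL segments, crossfaded over ~1.5 s so
    # activity changes look like continuous postural transitions rather
    # than instantaneous jumps no wearer could produce
    n_fade = int(round(1.5 * sample_rate))
    samples = np.empty((0, 3))
    while len(samples) < n_total:
        kind = kinds[rng.choice(len(kinds), p=weights)]
        if kind in ("lie_down", "stand_up"):
            seg = clip_to_range(_lying_bout(rng, sample_rate), sensor_range)
        else:
            dur = rng.uniform(8.0, 20.0)
            seg = simulate_adl(kind, rng, dur, sample_rate, sensor_range).samples
        if len(samples) >= n_fade and len(seg) > n_fade:
            w = np.linspace(0, 1, n_fade)[:, None]
            blended = samples[-n_fade:] * (1 - w) + seg[:n_fade] * w
            samples = np.vstack([samples[:-n_fade], blended, seg[n_fade:]])
        else:
            samples = np.vstack([samples, seg])
    samples = samples[:n_total]

    annotations: list[FallAnnotation] = []
    occupied: list[tuple[int, int]] = []
    for t_fall in fall_times:
        seg, ann = simulate_fall(fall_params, rng, sample_rate, sensor_range)
        impact_offset = int(round(ann.time * sample_rate))
        start = int(round(t_fall * sample_rate)) - impact_offset
        end = start + len(seg)
        if start < 0 or end > n_total:
            raise ValueError(
                f"fall at {t_fall} s does not fit in a {duration_s} s stream "
                "(needs room for pre-activity and the lying phase)"
            )
        if any(s < end and start < e for s, e in occupied):
            raise ValueError(f"fall at {t_fall} s overlaps a previous placement")
        occupied.append((start, end))
        samples[start:end] = seg.samples
        annotations.append(FallAnnotation((start + impact_offset) / sample_rate))

    stream = AccelStream(sample_rate, clip_to_range(samples, sensor_range),
                         subject_id=subject_id, sensor_range=sensor_range)
    return stream, annotations


# ---------------------------------------------------------------------------
# Dataset persistence (CSV dialects of the io module plus a manifest)
# ---------------------------------------------------------------------------

def save_protocol_dataset(trials: list[Trial], directory: str | Path) -> Path:
    """Write each trial as a stream CSV plus a ``manifest.csv`` of labels."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, trial in enumerate(trials):
        fname = f"trial_{i:04d}.csv"
        write_stream(trial.stream, directory / fname)
        rows.append({
            "file": fname,
            "participant": trial.participant,
            "category": trial.category,
            "label": trial.label,
            "trial_index": trial.trial_index,
            "annotation_time": trial.annotation.time if trial.annotation else "",
            "sample_rate": trial.stream.sample_rate,
            "sensor_range": trial.stream.sensor_range,
        })
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_protocol_dataset(directory: str | Path) -> list[Trial]:
    """Read a trial collection written by :func:`save_protocol_dataset`."""
    import pandas as pd

    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {directory}")
    df = pd.read_csv(manifest)
    trials = []
    for row in df.itertuples(index=False):
        stream = read_stream(directory / row.file, float(row.sample_rate),
                             float(row.sensor_range))
        ann = None
        if row.label == "fall" and not pd.isna(row.annotation_time):
            ann = FallAnnotation(float(row.annotation_time))
        trials.append(Trial(int(row.participant), str(row.category),
                            str(row.label), int(row.trial_index), stream, ann))
    return trials
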