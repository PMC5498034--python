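"""Synthetic signal generators: falls, near-falls, ADLs, protocol, streams."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fallkit as fk
from fallkit.classifier import trial_feature_vector
from fallkit.simulator import load_protocol_dataset, save_protocol_dataset


def magnitude(samples):
    return np.linalg.norm(samples, axis=1)


class TestSimulateFall:
    def test_peak_magnitude_at_annotation(self):
        stream, ann = fk.simulate_fall(rng=0)
        mag = magnitude(stream.samples)
        i = int(round(ann.time * stream.sample_rate))
        window = mag[max(i - 10, 0) : i + 10]
        assert window.max() >= 3.0

    def test_lying_phase_is_still_and_rotated(self):
        stream, ann = fk.simulate_fall(rng=1)
        rate = stream.sample_rate
        lie = stream.samples[int((ann.time + 2.0) * rate) :]
        active = stream.samples[: int(ann.time * rate)]
        assert np.all(np.abs(magnitude(lie) - 1.0) < 0.1)
        assert lie.var(axis=0).max() < active.var(axis=0).max()
        # gravity left the vertical axis
        assert abs(lie[:, 2].mean()) < 0.2

    def test_same_seed_reproducible(self):
        s1, a1 = fk.simulate_fall(rng=42)
        s2, a2 = fk.simulate_fall(rng=42)
        np.testing.assert_array_equal(s1.samples, s2.samples)
        assert a1 == a2

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            fk.FallSignatureParams(lying_s=0.0)
        with pytest.raises(ValueError):
            fk.FallSignatureParams(lying_axis=2)


class TestSimulateAdl:
    def test_walking_spectrum_peaks_near_gait_frequency(self):
        stream = fk.simulate_adl("walking", rng=3, duration_s=10.0)
        z = stream.samples[:, 2] - stream.samples[:, 2].mean()
        spectrum = np.abs(np.fft.rfft(z))
        freqs = np.fft.rfftfreq(len(z), 1.0 / stream.sample_rate)
        dominant = freqs[np.argmax(spectrum)]
        assert 1.5 <= dominant <= 2.5

    def test_sit_to_stand_peak_below_two_g(self):
        stream = fk.simulate_adl("sit_to_stand", rng=4)
        assert magnitude(stream.samples).max() < 2.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown ADL"):
            fk.simulate_adl("flying", rng=0)

    def test_same_seed_reproducible(self):
        s1 = fk.simulate_adl("walking", rng=9)
        s2 = fk.simulate_adl("walking", rng=9)
        np.testing.assert_array_equal(s1.samples, s2.samples)

    @pytest.mark.parametrize("kind", fk.ADL_KINDS)
    def test_all_kinds_produce_plausible_magnitudes(self, kind):
        stream = fk.simulate_adl(kind, rng=7)
        mag = magnitude(stream.samples)
        assert mag.max() < 2.5
        assert 0.5 < mag.mean() < 1.5


class TestSimulateNearFall:
    def test_spike_at_least_two_g(self):
        stream = fk.simulate_near_fall(rng=5)
        assert magnitude(stream.samples).max() >= 2.0

    def test_recovers_to_upright_activity(self):
        stream = fk.simulate_near_fall(rng=6)
        tail = stream.samples[-int(2.0 * stream.sample_rate) :]
        assert abs(magnitude(tail).mean() - 1.0) < 0.15
        assert tail.var(axis=0).sum() > 1e-3  # moving, not lying still

    def test_trained_model_rejects_most_near_falls(self, default_model):
        """Near-falls are the designed hard negatives: far fewer than half may alarm."""
        streams = [fk.simulate_near_fall(rng=100 + i) for i in range(40)]
        X = np.array([trial_feature_vector(s, fk.FALL) for s in streams])
        Xn = fk.apply_normalizer(default_model.normalizer, X)
        assert default_model.predict(Xn).mean() < 0.5


class TestProtocolDataset:
    def test_default_counts_match_protocol(self, default_trials):
        n_fall = sum(t.label == "fall" for t in default_trials)
        assert n_fall == 210
        assert len(default_trials) - n_fall == 390

    def test_minimal_spec_counts(self):
        trials = fk.generate_protocol_dataset(
            fk.ProtocolSpec(n_participants=1, trials_per_category=1)
        )
        assert sum(t.label == "fall" for t in trials) == 7
        assert sum(t.label == "non_fall" for t in trials) == 13

    def test_rerun_identical(self):
        spec = fk.ProtocolSpec(n_participants=1, trials_per_category=1, seed=11)
        t1 = fk.generate_protocol_dataset(spec)
        t2 = fk.generate_protocol_dataset(spec)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.stream.samples, b.stream.samples)
            assert a.category == b.category and a.label == b.label

    def test_fall_trials_carry_annotations(self, default_trials):
        for t in default_trials[:50]:
            if t.label == "fall":
                assert t.annotation is not None
                assert 0 <= t.annotation.time <= t.stream.duration_s
            else:
                assert t.annotation is None

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            fk.ProtocolSpec(n_participants=0)

    def test_save_load_round_trip(self, tmp_path):
        trials = fk.generate_protocol_dataset(
            fk.ProtocolSpec(n_participants=1, trials_per_category=1, seed=3)
        )
        save_protocol_dataset(trials, tmp_path / "proto")
        back = load_protocol_dataset(tmp_path / "proto")
        assert len(back) == len(trials)
        for a, b in zip(trials, back):
            assert (a.participant, a.category, a.label) == (b.participant, b.category, b.label)
            np.testing.assert_allclose(a.stream.samples, b.stream.samples, atol=1e-8)


class TestGenerateStream:
    def test_no_falls(self):
        stream, anns = fk.generate_stream(120.0, [], rng=0)
        assert anns == []
        assert len(stream) == 12000

    def test_three_falls_annotated_at_requested_times(self):
        times = [100.0, 200.0, 330.0]
        stream, anns = fk.generate_stream(400.0, times, rng=1)
        assert [a.time for a in anns] == pytest.approx(times, abs=0.02)

    def test_two_g_device_saturates_exactly(self):
        stream, _ = fk.generate_stream(200.0, [100.0], rng=2, sensor_range=2.0)
        assert np.abs(stream.samples).max() == pytest.approx(2.0)
        # the impact reaches the rail
        assert np.any(np.abs(stream.samples) >= 2.0)

    def test_close_falls_rejected(self):
        with pytest.raises(ValueError, match="60 s"):
            fk.generate_stream(400.0, [100.0, 150.0], rng=0)

    def test_fall_near_stream_edge_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            fk.generate_stream(100.0, [99.0], rng=0)

    def test_rerun_identical_with_integer_seed(self):
        s1, a1 = fk.generate_stream(120.0, [60.0], rng=21)
        s2, a2 = fk.generate_stream(120.0, [60.0], rng=21)
        np.testing.assert_array_equal(s1.samples, s2.samples)
        assert a1 == a2

    @settings(max_examples=15, deadline=None)
    @given(
        k=st.integers(0, 3),
        seed=st.integers(0, 2**16),
    )
    def test_annotation_count_equals_embedded_falls(self, k, seed):
        times = [90.0 + 80.0 * i for i in range(k)]
        stream, anns = fk.generate_stream(400.0, times, rng=seed)
        assert len(anns) == k
        assert len(stream) == 40000
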