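"""Spike detection, multimodal features, and the tracking decoder."""

import numpy as np
import pytest

from spikesight.decoder import (
    DetectionEvent,
    ProbeGeometry,
    build_feature_vector,
    decode_events,
    decode_stream,
    detect_events,
    evaluate_tracking,
    train_decoder,
)
from spikesight.synthetic import DEFAULT_ARCHETYPES, waveform_kernel

FS = 10_000.0


def inject(stream, kernel, pre, sample, channel_scales):
    for ch, scale in enumerate(channel_scales):
        stream[ch, sample - pre : sample - pre + kernel.size] += scale * kernel


class TestDetectEvents:
    def test_silent_stream_no_events(self, linear_probe):
        stream = np.random.default_rng(0).normal(0, 5.0, (8, 20_000))
        assert detect_events(stream, linear_probe, FS, threshold_mads=6.0) == []

    def test_all_zero_stream_no_events(self, linear_probe):
        assert detect_events(np.zeros((8, 5000)), linear_probe, FS) == []

    def test_single_injected_spike_found_on_its_channel(self, linear_probe):
        rng = np.random.default_rng(1)
        stream = rng.normal(0, 5.0, (8, 20_000))
        kernel, pre = waveform_kernel(DEFAULT_ARCHETYPES["SST"], FS, amplitude=50.0)
        inject(stream, kernel, pre, 10_000, [0, 0, 0, 1.0, 0.2, 0, 0, 0])
        events = detect_events(stream, linear_probe, FS, threshold_mads=5.0)
        assert len(events) == 1
        assert events[0].extremum_channel == 3
        assert abs(events[0].time - 1.0) < 1e-3

    def test_nearby_crossings_merge_to_largest_amplitude(self, linear_probe):
        stream = np.zeros((8, 20_000))
        stream += np.random.default_rng(2).normal(0, 1.0, stream.shape)
        kernel, pre = waveform_kernel(DEFAULT_ARCHETYPES["SST"], FS, amplitude=40.0)
        inject(stream, kernel, pre, 10_000, [0, 0.9, 0, 0, 0, 0, 0, 0])
        inject(stream, kernel, pre, 10_005, [0, 0, 1.0, 0, 0, 0, 0, 0])  # 0.5 ms later
        events = detect_events(stream, linear_probe, FS, threshold_mads=5.0, refractory_ms=1.0)
        assert len(events) == 1
        assert events[0].extremum_channel == 2

    def test_edge_events_skipped(self, linear_probe):
        stream = np.random.default_rng(3).normal(0, 1.0, (8, 2000))
        stream[0, 3] = -500.0  # crossing too close to the stream start for a full window
        events = detect_events(stream, linear_probe, FS, threshold_mads=6.0)
        assert events == []


class TestFeatureVectors:
    def event(self, geometry, channel=3):
        snippet = np.random.default_rng(0).standard_normal((geometry.n_channels, 30))
        return DetectionEvent(time=0.5, extremum_channel=channel, snippet_block=snippet)

    def test_single_neighbor_equals_extremum(self, linear_probe):
        ev = self.event(linear_probe)
        fv = build_feature_vector(ev, linear_probe, n_neighbors=1)
        np.testing.assert_array_equal(fv.neighborhood_block[0], fv.extremum_snippet)

    def test_linear_probe_neighbors_are_adjacent(self, linear_probe):
        ev = self.event(linear_probe, channel=4)
        fv = build_feature_vector(ev, linear_probe, n_neighbors=3)
        np.testing.assert_array_equal(
            fv.neighborhood_block, ev.snippet_block[[4, 3, 5]]
        )

    def test_neighbors_match_brute_force_knn(self):
        rng = np.random.default_rng(9)
        positions = rng.uniform(0, 100, (12, 2))
        geom = ProbeGeometry(tuple(range(12)), positions)
        for ch in range(12):
            got = geom.nearest_channels(ch, 5)
            d = np.linalg.norm(positions - positions[ch], axis=1)
            expected = sorted(range(12), key=lambda j: (d[j], j))[:5]
            np.testing.assert_array_equal(got, expected)

    def test_too_many_neighbors_rejected(self, linear_probe):
        with pytest.raises(ValueError):
            build_feature_vector(self.event(linear_probe), linear_probe, n_neighbors=9)


def make_labeled_features(geometry, n_per_unit=60, seed=0, amplitude=60.0):
    """Two well-separated units + noise snippets as DetectionEvents."""
    rng = np.random.default_rng(seed)
    events, labels = [], []
    k1, pre = waveform_kernel(DEFAULT_ARCHETYPES["Pyramidal"], FS, amplitude=amplitude)
    k2, _ = waveform_kernel(DEFAULT_ARCHETYPES["GABA_nonSST"], FS, amplitude=amplitude)
    for i in range(n_per_unit):
        for ch, kernel, label in ((1, k1, "u1"), (6, k2, "u2")):
            block = rng.normal(0, 3.0, (geometry.n_channels, k1.size))
            block[ch] += kernel
            events.append(DetectionEvent(0.01 * len(events), ch, block))
            labels.append(label)
        block = rng.normal(0, 3.0, (geometry.n_channels, k1.size))
        events.append(DetectionEvent(0.01 * len(events), int(rng.integers(0, 8)), block))
        labels.append("noise")
    return events, labels


class TestTrainDecode:
    def test_separable_units_train_to_high_accuracy(self, linear_probe):
        events, labels = make_labeled_features(linear_probe)
        model = train_decoder(events, labels, linear_probe, seed=0, max_iter=200)
        assert model.training_accuracy >= 0.99
        assert set(model.class_list) == {"u1", "u2", "noise"}
        assert model.class_list.count("noise") == 1

    def test_output_dimension_is_units_plus_noise(self, linear_probe):
        events, labels = make_labeled_features(linear_probe, n_per_unit=20)
        model = train_decoder(events, labels, linear_probe, seed=0, max_iter=100)
        assert len(model.model.classes_) == 3  # 2 day-1 units + noise

    def test_shuffled_labels_raise_training_loss(self, linear_probe):
        events, labels = make_labeled_features(linear_probe, n_per_unit=30)
        true_model = train_decoder(events, labels, linear_probe, seed=1, max_iter=150)
        rng = np.random.default_rng(1)
        shuffled = list(labels)
        rng.shuffle(shuffled)
        shuf_model = train_decoder(events, shuffled, linear_probe, seed=1, max_iter=150)
        assert shuf_model.model.loss_ >= true_model.model.loss_

    def test_single_class_rejected(self, linear_probe):
        events, _ = make_labeled_features(linear_probe, n_per_unit=5)
        with pytest.raises(ValueError, match="class"):
            train_decoder(events, ["u1"] * len(events), linear_probe)

    def test_memorization_recovers_training_labels(self, linear_probe):
        events, labels = make_labeled_features(linear_probe, n_per_unit=40)
        model = train_decoder(events, labels, linear_probe, seed=0, max_iter=200)
        pred = decode_events(model, events, linear_probe)
        assert np.mean(pred == np.asarray(labels)) >= 0.99

    def test_decode_stream_partitions_units_and_noise(self, linear_probe):
        events, labels = make_labeled_features(linear_probe, n_per_unit=30)
        model = train_decoder(events, labels, linear_probe, seed=0, max_iter=150)
        trains, noise_times = decode_stream(model, events, linear_probe, duration=10.0, sampling_rate=FS)
        assert set(trains) == {"u1", "u2"}
        n_assigned = sum(t.n_spikes for t in trains.values()) + len(noise_times)
        assert n_assigned == len(events)

    def test_empty_event_list(self, linear_probe):
        events, labels = make_labeled_features(linear_probe, n_per_unit=10)
        model = train_decoder(events, labels, linear_probe, seed=0, max_iter=50)
        trains, noise = decode_stream(model, [], linear_probe, duration=1.0, sampling_rate=FS)
        assert all(t.n_spikes == 0 for t in trains.values()) and noise == []

    def test_deterministic_given_seed(self, linear_probe):
        events, labels = make_labeled_features(linear_probe, n_per_unit=20)
        m1 = train_decoder(events, labels, linear_probe, seed=3, max_iter=100)
        m2 = train_decoder(events, labels, linear_probe, seed=3, max_iter=100)
        np.testing.assert_array_equal(
            decode_events(m1, events, linear_probe), decode_events(m2, events, linear_probe)
        )


class TestEvaluateTracking:
    def test_identity_predictions(self):
        truth = [(0.01 * i, f"u{i % 3}") for i in range(30)]
        m = evaluate_tracking(truth, truth)
        assert m["detection_accuracy"] == 1.0
        assert m["classification_accuracy"] == 1.0

    def test_no_predictions(self):
        truth = [(0.1, "u0"), (0.2, "u1")]
        m = evaluate_tracking([], truth)
        assert m["detection_accuracy"] == 0.0
        assert m["n_misses"] == 2

    def test_empty_truth_flags(self):
        m = evaluate_tracking([(0.1, "u0")], [])
        assert m["empty_truth"] and m["n_false_positives"] == 1

    def test_known_corruption_rate_recovered(self):
        rng = np.random.default_rng(5)
        truth = [(0.005 * i, f"u{i % 4}") for i in range(400)]
        predicted = []
        for i, (t, label) in enumerate(truth):
            if rng.random() < 0.05:
                label = f"u{(int(label[1]) + 1) % 4}"
            predicted.append((t + rng.uniform(-2e-4, 2e-4), label))
        m = evaluate_tracking(predicted, truth)
        assert m["detection_accuracy"] == 1.0
        assert abs(m["classification_accuracy"] - 0.95) < 0.03
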