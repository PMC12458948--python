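"""Day-1-supervised spike decoder for chronic unit tracking.

After a first session is spike-sorted, a single multi-class model is
trained on labeled spikes to distinguish one class per day-1 unit plus a
reserved ``noise`` class.  Each detected spike in a later session is
summarized by a multimodal feature vector — (1) waveform snippets from the
n nearest channels, (2) the extremum-channel snippet, (3) the standardized
spatial coordinates of the extremum channel — and assigned a unit (or
noise) by the model, so the same units are tracked across sessions without
re-sorting.  The model is a small multilayer perceptron trained with
categorical cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from sklearn.neural_network import MLPClassifier

from spikesight.ephys_features import SpikeTrain

NOISE_LABEL = "noise"


@dataclass(frozen=True)
class ProbeGeometry:
    """Electrode layout: unique channel ids and (x, y) positions in micrometers."""

    channel_ids: tuple
    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids must be unique")
        if pos.shape != (len(self.channel_ids), 2) or not np.all(np.isfinite(pos)):
            raise ValueError("positions must be a finite (n_channels, 2) array")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def nearest_channels(self, channel: int, n: int) -> np.ndarray:
        """Indices of the n channels nearest to ``channel`` (ties by index)."""
        d = np.linalg.norm(self.positions - self.positions[channel], axis=1)
        order = np.lexsort((np.arange(self.n_channels), d))
        return order[:n]


@dataclass(frozen=True)
class DetectionEvent:
    """A threshold-crossing event with its multi-channel snippet."""

    time: float
    extremum_channel: int
    snippet_block: np.ndarray  # channels x window samples (filtered uV)
    amplitude: float = 0.0


@dataclass(frozen=True)
class SpikeFeatureVector:
    """Flattened multimodal features of one detection event."""

    neighborhood_block: np.ndarray
    extremum_snippet: np.ndarray
    extremum_xy: np.ndarray

    def concatenate(self) -> np.ndarray:
        return np.concatenate(
            [self.neighborhood_block.ravel(), self.extremum_snippet, self.extremum_xy]
        )


@dataclass
class DecoderModel:
    """Trained multi-class spike classifier (day-1 units + noise)."""

    class_list: tuple
    model: MLPClassifier
    input_spec: dict
    training_config: dict
    coord_mean: np.ndarray = field(default_factory=lambda: np.zeros(2))
    coord_scale: np.ndarray = field(default_factory=lambda: np.ones(2))
    training_accuracy: float = 0.0
    per_class_recall: dict = field(default_factory=dict)


def detect_events(
    stream: np.ndarray,
    geometry: ProbeGeometry,
    sampling_rate: float,
    threshold_mads: float = 5.0,
    refractory_ms: float = 1.0,
    pre_ms: float = 1.0,
    post_ms: float = 2.0,
) -> list[DetectionEvent]:
    """Detect negative threshold crossings on a filtered multi-channel stream.

    Per-channel robust noise is the scaled median absolute deviation
    (MAD / 0.6745, the Gaussian-consistent estimate); a channel fires where
    it dips below ``-threshold_mads * noise``.  Crossings on nearby
    channels within the refractory window are merged, keeping the channel
    with the largest absolute amplitude.  Events whose snippet window is
    clipped by the stream edge are dropped.
    """
    stream = np.asarray(stream, dtype=float)
    if stream.ndim != 2 or stream.shape[0] != geometry.n_channels:
        raise ValueError("stream must be (n_channels, n_samples)")
    if threshold_mads <= 0:
        raise ValueError("threshold_mads must be positive")
    n_samples = stream.shape[1]
    pre = int(round(pre_ms * 1e-3 * sampling_rate))
    post = int(round(post_ms * 1e-3 * sampling_rate))
    refractory = int(round(refractory_ms * 1e-3 * sampling_rate))

    noise = np.median(np.abs(stream - np.median(stream, axis=1, keepdims=True)), axis=1) / 0.6745
    candidates = []  # (sample, channel, |amplitude|)
    for ch in range(geometry.n_channels):
        thr = threshold_mads * noise[ch]
        if thr == 0:
            continue
        peaks, props = find_peaks(-stream[ch], height=thr, distance=max(1, refractory))
        for p, h in zip(peaks, props["peak_heights"]):
            candidates.append((int(p), ch, float(h)))
    if not candidates:
        return []
    candidates.sort(key=lambda c: (c[0], c[1]))

    # merge crossings within the refractory window to the largest-amplitude channel
    merged = []
    current = [candidates[0]]
    for c in candidates[1:]:
        if c[0] - current[-1][0] <= refractory:
            current.append(c)
        else:
            merged.append(max(current, key=lambda c: c[2]))
            current = [c]
    merged.append(max(current, key=lambda c: c[2]))

    events = []
    for sample, ch, amp in merged:
        if sample - pre < 0 or sample + post > n_samples:
            continue  # edge event: skipped
        events.append(
            DetectionEvent(
                time=sample / sampling_rate,
                extremum_channel=ch,
                snippet_block=stream[:, sample - pre : sample + post].copy(),
                amplitude=amp,
            )
        )
    return events


def build_feature_vector(
    event: DetectionEvent,
    geometry: ProbeGeometry,
    n_neighbors: int = 4,
    coord_mean: np.ndarray | None = None,
    coord_scale: np.ndarray | None = None,
) -> SpikeFeatureVector:
    """Multimodal features: nearest-channel snippets, extremum snippet, position.

    Neighbor channels are the ``n_neighbors`` nearest to the extremum by
    Euclidean distance (ties broken by channel index), in fixed
    distance-then-id order.  Coordinates are standardized by the supplied
    training-set mean/scale (identity by default).
    """
    if n_neighbors > geometry.n_channels:
        raise ValueError("n_neighbors exceeds channel count")
    neighbors = geometry.nearest_channels(event.extremum_channel, n_neighbors)
    block = event.snippet_block[neighbors]
    xy = geometry.positions[event.extremum_channel].astype(float)
    mean = np.zeros(2) if coord_mean is None else np.asarray(coord_mean, float)
    scale = np.ones(2) if coord_scale is None else np.asarray(coord_scale, float)
    xy = (xy - mean) / np.where(scale == 0, 1.0, scale)
    return SpikeFeatureVector(
        neighborhood_block=block,
        extremum_snippet=event.snippet_block[event.extremum_channel],
        extremum_xy=xy,
    )


def _feature_matrix(events, geometry, n_neighbors, coord_mean, coord_scale) -> np.ndarray:
    return np.stack(
        [
            build_feature_vector(e, geometry, n_neighbors, coord_mean, coord_scale).concatenate()
            for e in events
        ]
    )


def train_decoder(
    events: list[DetectionEvent],
    labels: list,
    geometry: ProbeGeometry,
    n_neighbors: int = 4,
    hidden_layer_sizes: tuple = (256, 64),
    max_iter: int = 300,
    seed: int = 0,
) -> DecoderModel:
    """Train the day-1 multi-class spike decoder.

    ``labels`` assigns each event a day-1 unit id or the reserved
    ``"noise"`` label; every class needs at least one example and at least
    two classes must be present.  Training minimizes categorical
    cross-entropy; training-set accuracy and per-class recall are recorded
    on the returned model.
    """
    if len(events) != len(labels) or not events:
        raise ValueError("events and labels must be non-empty and aligned")
    y = np.asarray([str(l) for l in labels])
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("empty class: need noise plus >= 1 unit (>= 2 classes total)")
    if np.any(counts < 1):
        raise ValueError("empty class")

    xy = np.stack([geometry.positions[e.extremum_channel] for e in events])
    coord_mean = xy.mean(axis=0)
    coord_scale = xy.std(axis=0)
    coord_scale = np.where(coord_scale == 0, 1.0, coord_scale)

    X = _feature_matrix(events, geometry, n_neighbors, coord_mean, coord_scale)
    feat_scale = X.std(axis=0)
    feat_scale = np.where(feat_scale == 0, 1.0, feat_scale)
    feat_mean = X.mean(axis=0)
    Xs = (X - feat_mean) / feat_scale

    model = MLPClassifier(
        hidden_layer_sizes=hidden_layer_sizes,
        activation="relu",
        random_state=seed,
        max_iter=max_iter,
    )
    model.fit(Xs, y)
    pred = model.predict(Xs)
    recall = {
        c: float(np.mean(pred[y == c] == c)) for c in classes
    }
    class_list = tuple(c for c in classes if c != NOISE_LABEL) + (NOISE_LABEL,)
    return DecoderModel(
        class_list=class_list,
        model=model,
        input_spec={
            "n_neighbors": n_neighbors,
            "window": events[0].snippet_block.shape[1],
            "n_features": X.shape[1],
            "feature_mean": feat_mean,
            "feature_scale": feat_scale,
        },
        training_config={
            "hidden_layer_sizes": hidden_layer_sizes,
            "max_iter": max_iter,
            "seed": seed,
            "loss": "categorical_cross_entropy",
        },
        coord_mean=coord_mean,
        coord_scale=coord_scale,
        training_accuracy=float(np.mean(pred == y)),
        per_class_recall=recall,
    )


def decode_events(model: DecoderModel, events, geometry: ProbeGeometry) -> np.ndarray:
    """Predict a class label for every detection event."""
    if not events:
        return np.asarray([], dtype=object)
    X = _feature_matrix(
        events, geometry, model.input_spec["n_neighbors"], model.coord_mean, model.coord_scale
    )
    if X.shape[1] != model.input_spec["n_features"]:
        raise ValueError("input_spec violation: feature length mismatch")
    Xs = (X - model.input_spec["feature_mean"]) / model.input_spec["feature_scale"]
    return model.model.predict(Xs)


def decode_stream(
    model: DecoderModel,
    events: list[DetectionEvent],
    geometry: ProbeGeometry,
    duration: float,
    sampling_rate: float,
) -> tuple[dict, list]:
    """Assign events to day-1 units; return per-unit SpikeTrains + noise times.

    Noise-class events are excluded from the unit trains; every train is
    time-sorted.
    """
    pred = decode_events(model, events, geometry)
    unit_times: dict = {u: [] for u in model.class_list if u != NOISE_LABEL}
    noise_times = []
    for e, p in zip(events, pred):
        if p == NOISE_LABEL:
            noise_times.append(e.time)
        else:
            unit_times[p].append(e.time)
    trains = {
        u: SpikeTrain(u, np.unique(np.asarray(t)), duration=duration, sampling_rate=sampling_rate)
        for u, t in unit_times.items()
    }
    return trains, sorted(noise_times)


def evaluate_tracking(
    predicted: list[tuple[float, object]],
    truth: list[tuple[float, object]],
    match_window_s: float = 0.5e-3,
) -> dict:
    """Matched-event detection and classification accuracy.

    Events are matched greedily by nearest time within ``match_window_s``.
    Unmatched truth events are misses; unmatched predictions are false
    positives.  ``detection_accuracy`` is matched-truth fraction;
    ``classification_accuracy`` is the correct-label fraction among
    matched events.
    """
    if not truth:
        return {
            "detection_accuracy": 0.0,
            "classification_accuracy": 0.0,
            "n_matched": 0,
            "n_misses": 0,
            "n_false_positives": len(predicted),
            "confusion": {},
            "empty_truth": True,
        }
    pred_sorted = sorted(predicted)
    truth_sorted = sorted(truth)
    used = np.zeros(len(pred_sorted), dtype=bool)
    pred_times = np.array([t for t, _ in pred_sorted]) if pred_sorted else np.empty(0)
    matches = []
    for t_time, t_label in truth_sorted:
        if pred_times.size == 0:
            continue
        j = int(np.searchsorted(pred_times, t_time))
        best, best_dt = -1, match_window_s
        for cand in (j - 1, j, j + 1):
            if 0 <= cand < len(pred_sorted) and not used[cand]:
                dt = abs(pred_times[cand] - t_time)
                if dt <= best_dt:
                    best, best_dt = cand, dt
        if best >= 0:
            used[best] = True
            matches.append((t_label, pred_sorted[best][1]))
    n_matched = len(matches)
    confusion: dict = {}
    correct = 0
    for t_label, p_label in matches:
        confusion[(t_label, p_label)] = confusion.get((t_label, p_label), 0) + 1
        correct += t_label == p_label
    return {
        "detection_accuracy": n_matched / len(truth_sorted),
        "classification_accuracy": correct / n_matched if n_matched else 0.0,
        "n_matched": n_matched,
        "n_misses": len(truth_sorted) - n_matched,
        "n_false_positives": int(len(pred_sorted) - n_matched),
        "confusion": confusion,
        "empty_truth": False,
    }
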