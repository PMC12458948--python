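"""Chronic unit tracking: train a spike decoder on day 1, decode a drifted day 2.

Simulates a 5-unit, 16-channel, 60 s recording; detects spikes; trains the
multi-class decoder (one class per day-1 unit + noise) on day-1 labels;
then decodes an independent second session whose spike amplitudes drift
down by 10% — the chronic-instability regime the decoder must survive.
"""

import dataclasses

import numpy as np

import spikesight as ss
from spikesight.decoder import decode_events
from spikesight.synthetic import sample_noise_events

fs = 10_000.0
geometry = ss.ProbeGeometry(
    tuple(range(16)),
    np.column_stack([np.tile([0.0, 20.0], 8), np.repeat(np.arange(8) * 20.0, 2)]),
)
archetypes = [
    ss.DEFAULT_ARCHETYPES[k]
    for k in ("Pyramidal", "SST", "GABA_nonSST", "Juxtacellular", "Axo_axonic")
]
units = tuple((archetypes[i], (10.0, 15.0 + 30 * i), 120.0) for i in range(5))
cfg = ss.RecordingSimConfig(
    geometry=geometry, units=units, noise_sd=8.0, duration=60.0, sampling_rate=fs, seed=0
)

stream, truth = ss.synth_recording(cfg)
events = ss.detect_events(stream, geometry, fs, threshold_mads=5.0)
print(f"day 1: {len(truth)} true spikes, {len(events)} detected events")

truth_times = np.array([t for t, _ in truth])
truth_labels = [u for _, u in truth]
labels = []
for e in events:
    j = np.searchsorted(truth_times, e.time)
    cand = [(abs(truth_times[c] - e.time), c) for c in (j - 1, j) if 0 <= c < len(truth_times)]
    dt, c = min(cand)
    labels.append(truth_labels[c] if dt < 0.5e-3 else "noise")
noise_events = sample_noise_events(stream, geometry, fs, 150, seed=77, exclude_times=truth)
model = ss.train_decoder(
    events + noise_events, labels + ["noise"] * len(noise_events), geometry, seed=0
)
print(f"decoder classes: {len(model.class_list)} (5 units + noise), "
      f"training accuracy {model.training_accuracy:.3f}")

cfg2 = dataclasses.replace(cfg, seed=1000, amplitude_drift=-0.10)
stream2, truth2 = ss.synth_recording(cfg2)
events2 = ss.detect_events(stream2, geometry, fs, threshold_mads=5.0)
pred = decode_events(model, events2, geometry)
metrics = ss.evaluate_tracking(
    [(e.time, p) for e, p in zip(events2, pred) if p != "noise"], truth2
)
print(f"day 2 (10% amplitude drift): detection accuracy "
      f"{metrics['detection_accuracy']:.3f}, classification accuracy "
      f"{metrics['classification_accuracy']:.3f} on {metrics['n_matched']} matched spikes")
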