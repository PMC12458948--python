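"""Readers and writers for spike-sorter-style output directories.

Directory layout (phy-like, plain NPY + JSON/CSV):

    spike_samples.npy     int64, sample index of every spike (all units pooled)
    spike_clusters.npy    int64, cluster id of every spike (aligned to above)
    templates.npy         float, (n_units, n_channels, n_time) microvolts
    channel_positions.csv columns: channel_id, x_um, y_um
    params.json           sampling_rate, duration_s, pre_samples, unit_ids

A plain two-column CSV dialect (unit_id, spike_time_s) is supported for toy
inputs via :func:`read_spike_csv`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from spikesight.decoder import ProbeGeometry
from spikesight.ephys_features import (
    NeuronRecord,
    SpikeTrain,
    WaveformTemplate,
    build_record,
)


def read_channel_geometry(path: str | Path) -> ProbeGeometry:
    """Read channel geometry from a CSV (channel_id, x_um, y_um) or JSON file."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        ids = [row["channel_id"] for row in payload]
        xy = np.array([[row["x_um"], row["y_um"]] for row in payload], dtype=float)
    else:
        table = pd.read_csv(path)
        ids = table["channel_id"].tolist()
        xy = table[["x_um", "y_um"]].to_numpy(dtype=float)
    return ProbeGeometry(channel_ids=tuple(ids), positions=xy)


def write_channel_geometry(geometry: ProbeGeometry, path: str | Path) -> None:
    pd.DataFrame(
        {
            "channel_id": list(geometry.channel_ids),
            "x_um": geometry.positions[:, 0],
            "y_um": geometry.positions[:, 1],
        }
    ).to_csv(path, index=False)


def write_sorter_dir(
    out_dir: str | Path,
    spike_times_s: dict,
    templates: dict,
    geometry: ProbeGeometry,
    sampling_rate: float,
    duration_s: float,
    pre_samples: int,
) -> Path:
    """Write per-unit spike times and templates in the sorter directory layout."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unit_ids = sorted(spike_times_s)
    samples, clusters = [], []
    for k, uid in enumerate(unit_ids):
        st = np.asarray(spike_times_s[uid], dtype=float)
        samples.append(np.round(st * sampling_rate).astype(np.int64))
        clusters.append(np.full(st.size, k, dtype=np.int64))
    samples = np.concatenate(samples) if samples else np.empty(0, np.int64)
    clusters = np.concatenate(clusters) if clusters else np.empty(0, np.int64)
    order = np.argsort(samples, kind="stable")
    np.save(out_dir / "spike_samples.npy", samples[order])
    np.save(out_dir / "spike_clusters.npy", clusters[order])
    np.save(
        out_dir / "templates.npy",
        np.stack([np.asarray(templates[uid], dtype=float) for uid in unit_ids]),
    )
    write_channel_geometry(geometry, out_dir / "channel_positions.csv")
    (out_dir / "params.json").write_text(
        json.dumps(
            {
                "sampling_rate": sampling_rate,
                "duration_s": duration_s,
                "pre_samples": pre_samples,
                "unit_ids": [str(u) for u in unit_ids],
            },
            indent=2,
        )
    )
    return out_dir


def read_sorter_dir(
    in_dir: str | Path,
    isi_bin_ms: float = 1.0,
    isi_max_ms: float = 100.0,
    acg_bin_ms: float = 1.0,
    acg_window_ms: float = 50.0,
) -> list[NeuronRecord]:
    """Load a sorter output directory into labeled-less NeuronRecords.

    ISI histograms and autocorrelograms are computed on load with the given
    binning (package defaults: 1 ms bins, ISI range 100 ms, ACG window
    +/-50 ms).
    """
    in_dir = Path(in_dir)
    params = json.loads((in_dir / "params.json").read_text())
    samples = np.load(in_dir / "spike_samples.npy")
    clusters = np.load(in_dir / "spike_clusters.npy")
    templates = np.load(in_dir / "templates.npy")
    fs = float(params["sampling_rate"])
    duration = float(params["duration_s"])
    pre = int(params["pre_samples"])
    records = []
    for k, uid in enumerate(params["unit_ids"]):
        times = np.sort(samples[clusters == k]) / fs
        times = times[(times >= 0) & (times <= duration)]
        tmpl = templates[k]
        peak_channel = int(np.argmax(tmpl.max(axis=1) - tmpl.min(axis=1)))
        train = SpikeTrain(uid, times, duration=duration, sampling_rate=fs)
        template = WaveformTemplate(
            uid, tmpl, sampling_rate=fs, pre_samples=pre, peak_channel=peak_channel
        )
        records.append(
            build_record(train, template, isi_bin_ms, isi_max_ms, acg_bin_ms, acg_window_ms)
        )
    return records


def read_spike_csv(path: str | Path, duration: float, sampling_rate: float = 30_000.0):
    """Read the toy CSV dialect (unit_id, spike_time_s) into SpikeTrains."""
    table = pd.read_csv(path)
    trains = []
    for uid, group in table.groupby("unit_id", sort=True):
        times = np.sort(group["spike_time_s"].to_numpy(dtype=float))
        trains.append(SpikeTrain(uid, times, duration=duration, sampling_rate=sampling_rate))
    return trains
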