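"""Seeded generators of archetyped neurons, recordings, and latent sessions.

Every generator is a pure function of its configuration and seed.  The
archetypes encode the classic extracellular distinctions: excitatory
pyramidal cells have a broad waveform with a deep initial negative
deflection, a slow-rising positive peak and a pronounced
afterhyperpolarization, and fire slowly and irregularly, often in bursts;
fast-spiking (non-SST) GABAergic interneurons have a steep, narrow
negative deflection and sustain high regular rates; SST interneurons and
the juxtacellular / axo-axonic categories fall between.  Spike trains are
gamma renewal processes with a hard refractory floor and an optional
burst-doublet mechanism; none of this is meant as biophysics, only as a
substrate with the right feature geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from spikesight.decoder import DetectionEvent, ProbeGeometry
from spikesight.ephys_features import (
    NeuronRecord,
    SpikeTrain,
    WaveformTemplate,
    build_record,
)

#: Spatial decay constant of extracellular amplitude with distance (um).
DEFAULT_LAMBDA_UM = 25.0


@dataclass(frozen=True)
class CellTypeArchetype:
    """Parameterized waveform/firing archetype of one cell-type class."""

    label: str
    trough_width_ms: float
    peak_to_trough_ms: float
    ahp_amplitude_fraction: float
    mean_rate_hz: float
    cv_isi: float
    burst_fraction: float
    refractory_ms: float

    def __post_init__(self) -> None:
        if self.trough_width_ms <= 0 or self.peak_to_trough_ms <= 0:
            raise ValueError("widths must be positive")
        if not 0 <= self.burst_fraction <= 1:
            raise ValueError("burst_fraction must be in [0, 1]")
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be positive")


DEFAULT_ARCHETYPES = {
    "Pyramidal": CellTypeArchetype("Pyramidal", 0.45, 0.80, 0.45, 2.5, 1.1, 0.20, 2.0),
    "SST": CellTypeArchetype("SST", 0.30, 0.55, 0.30, 6.0, 1.0, 0.10, 1.5),
    "GABA_nonSST": CellTypeArchetype("GABA_nonSST", 0.18, 0.32, 0.20, 15.0, 0.8, 0.05, 1.0),
    "Juxtacellular": CellTypeArchetype("Juxtacellular", 0.60, 1.05, 0.35, 3.5, 1.0, 0.15, 2.0),
    "Axo_axonic": CellTypeArchetype("Axo_axonic", 0.22, 0.40, 0.25, 10.0, 0.9, 0.05, 1.0),
}


@dataclass(frozen=True)
class RecordingSimConfig:
    """Configuration of a simulated multi-channel recording."""

    geometry: ProbeGeometry
    units: tuple  # of (archetype, (x_um, y_um), amplitude_uV)
    noise_sd: float = 10.0
    amplitude_drift: float = 0.0  # linear relative change over the session
    duration: float = 60.0
    sampling_rate: float = 10_000.0
    seed: int = 0
    decay_lambda_um: float = DEFAULT_LAMBDA_UM

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def waveform_kernel(
    archetype: CellTypeArchetype,
    sampling_rate: float = 30_000.0,
    pre_ms: float = 1.0,
    post_ms: float = 2.0,
    amplitude: float = 100.0,
) -> tuple[np.ndarray, int]:
    """Biphasic single-channel kernel (trough then AHP) for an archetype.

    Returns ``(samples, pre_samples)`` with the trough at the alignment
    point.  The trough is a negative Gaussian lobe whose FWHM equals
    ``trough_width_ms``; the afterhyperpolarization is a broader positive
    lobe centered ``peak_to_trough_ms`` later with relative amplitude
    ``ahp_amplitude_fraction``.
    """
    pre = int(round(pre_ms * 1e-3 * sampling_rate))
    post = int(round(post_ms * 1e-3 * sampling_rate))
    t_ms = (np.arange(pre + post) - pre) / sampling_rate * 1e3
    sigma_t = archetype.trough_width_ms / 2.355  # FWHM -> sigma
    sigma_p = archetype.trough_width_ms  # AHP lobe is broader than the trough
    wf = -amplitude * np.exp(-0.5 * (t_ms / sigma_t) ** 2)
    wf += (
        archetype.ahp_amplitude_fraction
        * amplitude
        * np.exp(-0.5 * ((t_ms - archetype.peak_to_trough_ms) / sigma_p) ** 2)
    )
    return wf, pre


def synth_spike_train(
    archetype: CellTypeArchetype, duration: float, rng: np.random.Generator,
    unit_id: object = "u0", sampling_rate: float = 30_000.0,
) -> SpikeTrain:
    """Gamma-renewal spike train with refractory floor and burst doublets.

    The base renewal rate is deflated by (1 + burst_fraction) so that the
    total rate, bursts included, matches ``mean_rate_hz`` in expectation.
    """
    rate = archetype.mean_rate_hz / (1.0 + archetype.burst_fraction)
    mean_isi = 1.0 / rate
    refr = archetype.refractory_ms * 1e-3
    free = max(mean_isi - refr, 1e-4)
    shape = 1.0 / max(archetype.cv_isi, 0.05) ** 2
    times = []
    t = rng.exponential(mean_isi)
    while t < duration:
        times.append(t)
        if archetype.burst_fraction and rng.random() < archetype.burst_fraction:
            t_b = t + refr + rng.exponential(refr / 2)
            if t_b < duration:
                times.append(t_b)
                t = t_b
        t = t + refr + rng.gamma(shape, free / shape)
    return SpikeTrain(unit_id, np.asarray(times), duration=duration, sampling_rate=sampling_rate)


def synth_neuron(
    archetype: CellTypeArchetype,
    duration: float = 120.0,
    seed: int = 0,
    unit_id: object = None,
    n_channels: int = 4,
    amplitude: float = 100.0,
    waveform_noise_sd: float = 1.5,
    sampling_rate: float = 30_000.0,
) -> NeuronRecord:
    """One labeled NeuronRecord drawn from an archetype.

    The template places the unit at channel 0 of a small linear footprint
    with exponential spatial decay; a little seeded waveform noise keeps
    records of one class from being pixel-identical.  A duration too short
    for two expected spikes sets ``metadata["short_duration_warning"]``.
    """
    rng = np.random.default_rng(seed)
    if unit_id is None:
        unit_id = f"{archetype.label}_{seed}"
    train = synth_spike_train(archetype, duration, rng, unit_id, sampling_rate)
    kernel, pre = waveform_kernel(archetype, sampling_rate, amplitude=amplitude)
    dists = np.arange(n_channels) * 20.0  # 20 um channel pitch from the unit
    scales = np.exp(-dists / DEFAULT_LAMBDA_UM)
    samples = np.outer(scales, kernel)
    samples += rng.normal(0.0, waveform_noise_sd, samples.shape)
    template = WaveformTemplate(
        unit_id, samples, sampling_rate=sampling_rate, pre_samples=pre,
        peak_channel=int(np.argmax(samples.max(axis=1) - samples.min(axis=1))),
    )
    metadata = {"archetype": archetype.label}
    if train.n_spikes < 2:
        metadata["short_duration_warning"] = True
    return build_record(train, template, label=archetype.label, metadata=metadata)


#: Relative parameter jitter per separation level.  At "separable" the
#: jittered trough-width / rate ranges of the default archetypes stay
#: disjoint across classes; at "hard" they overlap.
_JITTER = {"separable": 0.08, "hard": 0.35}


def synth_population(
    n_per_type: int = 20,
    separation_level: str = "separable",
    seed: int = 0,
    types: tuple = ("Pyramidal", "SST", "GABA_nonSST", "Juxtacellular"),
    duration: float = 120.0,
) -> list[NeuronRecord]:
    """Labeled population with per-record jittered archetype parameters."""
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    if separation_level not in _JITTER:
        raise ValueError("separation_level must be 'separable' or 'hard'")
    jitter = _JITTER[separation_level]
    rng = np.random.default_rng(seed)
    records = []
    for label in types:
        if label not in DEFAULT_ARCHETYPES:
            raise ValueError(f"unknown archetype {label!r}")
        base = DEFAULT_ARCHETYPES[label]
        for i in range(n_per_type):
            u = lambda: 1.0 + jitter * (2 * rng.random() - 1)
            arch = replace(
                base,
                trough_width_ms=base.trough_width_ms * u(),
                peak_to_trough_ms=base.peak_to_trough_ms * u(),
                ahp_amplitude_fraction=base.ahp_amplitude_fraction * u(),
                mean_rate_hz=base.mean_rate_hz * u(),
                cv_isi=base.cv_isi * u(),
            )
            rec_seed = int(rng.integers(0, 2**31 - 1))
            records.append(
                synth_neuron(arch, duration=duration, seed=rec_seed, unit_id=f"{label}_{i}")
            )
    return records


def archetype_overlap(level: str, param: str = "trough_width_ms") -> dict:
    """Configured parameter ranges per type at a separation level."""
    jitter = _JITTER[level]
    return {
        label: (getattr(a, param) * (1 - jitter), getattr(a, param) * (1 + jitter))
        for label, a in DEFAULT_ARCHETYPES.items()
    }


def synth_recording(config: RecordingSimConfig):
    """Simulated multi-channel voltage stream plus ground-truth events.

    Each unit's spikes are inserted as spatially decaying footprints
    (amplitude ~ exp(-distance / lambda)) on top of white noise; a linear
    amplitude drift over the session emulates chronic instability.

    Returns ``(stream, truth)`` with ``stream`` a (n_channels, n_samples)
    float array and ``truth`` a list of ``(time_s, unit_id)``.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_samples = int(round(config.duration * fs))
    n_channels = config.geometry.n_channels
    stream = rng.normal(0.0, config.noise_sd, (n_channels, n_samples)) if config.noise_sd > 0 \
        else np.zeros((n_channels, n_samples))
    truth = []
    for u, (archetype, location, amplitude) in enumerate(config.units):
        loc = np.asarray(location, dtype=float)
        if np.any(loc < config.geometry.positions.min(axis=0) - 200) or np.any(
            loc > config.geometry.positions.max(axis=0) + 200
        ):
            import warnings

            warnings.warn(f"unit {u} located > 200 um off the probe bounding box")
        unit_id = f"unit{u}"
        kernel, pre = waveform_kernel(archetype, fs, amplitude=1.0)
        dists = np.linalg.norm(config.geometry.positions - loc, axis=1)
        scales = amplitude * np.exp(-dists / config.decay_lambda_um)
        train = synth_spike_train(
            archetype, config.duration, rng, unit_id, sampling_rate=fs
        )
        for t in train.spike_times:
            s = int(round(t * fs))
            start, stop = s - pre, s - pre + kernel.size
            if start < 0 or stop > n_samples:
                continue
            drift_scale = 1.0 + config.amplitude_drift * (t / config.duration)
            stream[:, start:stop] += drift_scale * np.outer(scales, kernel)
            truth.append((s / fs, unit_id))
    truth.sort()
    return stream, truth


def sample_noise_events(
    stream: np.ndarray,
    geometry: ProbeGeometry,
    sampling_rate: float,
    n_events: int,
    seed: int = 0,
    exclude_times=None,
    exclusion_ms: float = 3.0,
    pre_ms: float = 1.0,
    post_ms: float = 2.0,
) -> list[DetectionEvent]:
    """Random-segment noise exemplars for the decoder's reserved noise class."""
    rng = np.random.default_rng(seed)
    pre = int(round(pre_ms * 1e-3 * sampling_rate))
    post = int(round(post_ms * 1e-3 * sampling_rate))
    n_samples = stream.shape[1]
    excl = np.sort(np.asarray([t for t, *_ in exclude_times] if exclude_times else []))
    events = []
    attempts = 0
    while len(events) < n_events and attempts < 50 * n_events:
        attempts += 1
        s = int(rng.integers(pre, n_samples - post))
        t = s / sampling_rate
        if excl.size:
            j = np.searchsorted(excl, t)
            near = [excl[k] for k in (j - 1, j) if 0 <= k < excl.size]
            if near and min(abs(t - v) for v in near) < exclusion_ms * 1e-3:
                continue
        ch = int(rng.integers(0, geometry.n_channels))
        events.append(
            DetectionEvent(
                time=t,
                extremum_channel=ch,
                snippet_block=stream[:, s - pre : s + post].copy(),
            )
        )
    return events


def synth_latent_session(
    d_latent: int = 2,
    n_units: int = 10,
    mixing_seed: int = 0,
    noise_sd: float = 1.0,
    duration: float = 500.0,
    bin_width: float = 0.1,
    base_rate_hz: float = 10.0,
    poisson: bool = True,
):
    """Low-rank latent dynamics mixed into per-unit rates, Poisson-sampled.

    Latents are unit-variance Gaussian-smoothed noise; a seeded positive
    full-rank loading matrix mixes them into per-unit rates around
    ``base_rate_hz``.  With ``poisson=True`` counts are Poisson samples of
    the (positive, clipped) rates; with ``poisson=False`` the mixed latent
    matrix plus ``noise_sd`` white noise is returned directly, so at
    ``noise_sd=0`` the activity matrix has rank exactly ``d_latent``.

    Returns ``(PopulationActivityMatrix, latents)`` with latents of shape
    (n_bins, d_latent).
    """
    from scipy.ndimage import gaussian_filter1d

    from spikesight.manifold import PopulationActivityMatrix

    if d_latent > n_units:
        raise ValueError("d_latent must not exceed n_units")
    rng = np.random.default_rng(mixing_seed)
    n_bins = int(round(duration / bin_width))
    raw = rng.standard_normal((n_bins, d_latent))
    latents = gaussian_filter1d(raw, sigma=10.0, axis=0)
    latents /= latents.std(axis=0, keepdims=True)
    loading = rng.uniform(0.5, 1.5, (n_units, d_latent))
    if poisson:
        # positive rates: latents enter multiplicatively around the base rate
        rates = base_rate_hz * np.clip(
            1.0 + 0.3 * (latents @ loading.T) / np.sqrt(d_latent), 0.05, None
        )
        counts = rng.poisson(rates * bin_width).astype(float)
    else:
        counts = latents @ loading.T
        if noise_sd > 0:
            counts = counts + rng.normal(0.0, noise_sd, counts.shape)
    bin_times = (np.arange(n_bins) + 0.5) * bin_width
    activity = PopulationActivityMatrix(
        bin_times=bin_times, counts=counts, bin_width=bin_width,
        unit_ids=tuple(f"u{j}" for j in range(n_units)),
    )
    return activity, latents
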