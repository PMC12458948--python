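"""Per-unit electrophysiological features: waveform template, ISI histogram, ACG.

These three objects are the classifier's raw material.  Spike times are
stored in seconds everywhere inside the package; milliseconds appear only
at the feature/report boundary (histogram bin edges, lag windows).

Binning convention: half-open bins ``[lo, hi)``, left edge inclusive.  The
autocorrelogram's negative-lag side uses the mirrored convention
``(lo, hi]`` so that the histogram is exactly symmetric about zero lag even
when spike-time differences fall on bin edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Closed cell-type label vocabulary.  ``GABA_nonSST`` groups the PV, VIP,
#: VGAT and PV/VGAT molecular subclasses into one GABAergic (non-SST) class.
CELL_TYPE_VOCABULARY = (
    "Pyramidal",
    "SST",
    "GABA_nonSST",
    "Juxtacellular",
    "Axo_axonic",
    "Unknown",
)


@dataclass(frozen=True)
class SpikeTrain:
    """Event times of one sorted unit.

    Parameters
    ----------
    unit_id
        Opaque unit identifier.
    spike_times
        Strictly increasing event times in seconds, all within
        ``[0, duration]``.
    duration
        Recording length in seconds.
    sampling_rate
        Acquisition rate in Hz.
    """

    unit_id: object
    spike_times: np.ndarray
    duration: float
    sampling_rate: float

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike_times must be strictly increasing")
            if times[0] < 0 or times[-1] > self.duration:
                raise ValueError("spike_times must lie in [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def rate(self) -> float:
        """Mean firing rate in Hz (0 for an empty recording)."""
        return self.n_spikes / self.duration if self.duration > 0 else 0.0


@dataclass(frozen=True)
class WaveformTemplate:
    """Trough-aligned mean extracellular spike shape across channels.

    ``samples`` is a channels x time matrix in microvolts; ``pre_samples``
    is the number of samples before the alignment point (the most negative
    sample on ``peak_channel``).
    """

    unit_id: object
    samples: np.ndarray
    sampling_rate: float
    pre_samples: int
    peak_channel: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if not np.all(np.isfinite(samples)):
            raise ValueError("template samples must be finite")
        n_channels, n_time = samples.shape
        if not 0 <= self.peak_channel < n_channels:
            raise ValueError("peak_channel out of range")
        if not 0 <= self.pre_samples < n_time:
            raise ValueError("pre_samples out of range")

    @property
    def peak_waveform(self) -> np.ndarray:
        """The single-channel waveform on the extremum channel."""
        return self.samples[self.peak_channel]

    @property
    def n_channels(self) -> int:
        return int(self.samples.shape[0])


@dataclass(frozen=True)
class ISIHistogram:
    """Histogram of consecutive-spike intervals (milliseconds)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_spikes: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        widths = np.diff(edges)
        if edges.size < 2 or np.any(widths <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if not np.allclose(widths, widths[0]):
            raise ValueError("bin_edges must be uniform")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.size != edges.size - 1:
            raise ValueError("counts length must match bin count")


@dataclass(frozen=True)
class Autocorrelogram:
    """Histogram of pairwise spike-time differences within a lag window.

    Self-pairs (zero lag) are excluded; counts are symmetric about zero.
    """

    lag_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.lag_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "lag_edges", edges)
        object.__setattr__(self, "counts", counts)
        widths = np.diff(edges)
        if edges.size < 2 or np.any(widths <= 0):
            raise ValueError("lag_edges must be strictly increasing")
        if not np.allclose(widths, widths[0]):
            raise ValueError("lag_edges must be uniform")
        if not np.isclose(edges[0], -edges[-1]):
            raise ValueError("lag_edges must be symmetric about 0")
        if counts.size != edges.size - 1:
            raise ValueError("counts length must match bin count")


@dataclass
class NeuronRecord:
    """One unit's spike train, features, and optional cell-type label."""

    unit_id: object
    spike_train: SpikeTrain
    template: WaveformTemplate
    isi: ISIHistogram
    acg: Autocorrelogram
    label: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in CELL_TYPE_VOCABULARY:
            raise ValueError(
                f"label {self.label!r} not in vocabulary {CELL_TYPE_VOCABULARY}"
            )
        for sub in (self.spike_train, self.template):
            if sub.unit_id != self.unit_id:
                raise ValueError("sub-object unit_id mismatch")


def extract_waveform_template(
    snippets: np.ndarray, pre_samples: int, unit_id: object = None,
    sampling_rate: float = 30_000.0,
) -> WaveformTemplate:
    """Average per-spike snippets into a mean template.

    Parameters
    ----------
    snippets
        Array of shape (n_spikes, n_channels, n_time), all spikes aligned
        at ``pre_samples``.
    pre_samples
        Samples before the alignment point.

    Returns
    -------
    WaveformTemplate
        Elementwise mean over snippets; ``peak_channel`` is the channel
        with the largest peak-to-trough amplitude (ties resolved to the
        lowest channel index).
    """
    snippets = np.asarray(snippets, dtype=float)
    if snippets.ndim != 3 or snippets.shape[0] == 0:
        raise ValueError("no spikes: need >= 1 snippet of shape (channels, time)")
    template = snippets.mean(axis=0)
    amplitude = template.max(axis=1) - template.min(axis=1)
    peak_channel = int(np.argmax(amplitude))  # argmax takes the lowest index on ties
    return WaveformTemplate(
        unit_id=unit_id,
        samples=template,
        sampling_rate=sampling_rate,
        pre_samples=int(pre_samples),
        peak_channel=peak_channel,
    )


def compute_isi_histogram(
    train: SpikeTrain, bin_width_ms: float = 1.0, max_isi_ms: float = 100.0
) -> ISIHistogram:
    """Histogram of consecutive inter-spike intervals.

    Intervals >= ``max_isi_ms`` are discarded.  A train with fewer than two
    spikes yields all-zero counts.
    """
    if bin_width_ms <= 0:
        raise ValueError("bin_width_ms must be positive")
    n_bins = _uniform_bin_count(max_isi_ms, bin_width_ms, "max_isi_ms")
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_ms
    counts = np.zeros(n_bins, dtype=np.int64)
    times = train.spike_times
    if times.size >= 2:
        isis_ms = np.diff(times) * 1000.0
        idx = np.floor(isis_ms / bin_width_ms).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        counts = np.bincount(idx, minlength=n_bins).astype(np.int64)
    return ISIHistogram(bin_edges=edges, counts=counts, n_spikes=times.size)


def compute_autocorrelogram(
    train: SpikeTrain, bin_width_ms: float = 1.0, window_ms: float = 50.0
) -> Autocorrelogram:
    """Autocorrelogram over ordered spike pairs with |dt| < ``window_ms``.

    Positive lags are binned half-open ``[lo, hi)``; the negative side is
    the exact mirror, so ``counts`` is symmetric by construction (every
    ordered pair (i, j) appears once with +dt and once with -dt).
    """
    if bin_width_ms <= 0:
        raise ValueError("bin_width_ms must be positive")
    n_half = _uniform_bin_count(window_ms, bin_width_ms, "window_ms")
    edges = np.arange(-n_half, n_half + 1, dtype=float) * bin_width_ms
    pos = np.zeros(n_half, dtype=np.int64)
    times_ms = train.spike_times * 1000.0
    n = times_ms.size
    if n >= 2:
        # sorted times: for each spike, later spikes within the window
        hi = np.searchsorted(times_ms, times_ms + window_ms, side="left")
        for i in range(n):
            if hi[i] <= i + 1:
                continue
            d = times_ms[i + 1 : hi[i]] - times_ms[i]
            idx = np.floor(d / bin_width_ms).astype(np.int64)
            idx = idx[idx < n_half]
            pos += np.bincount(idx, minlength=n_half).astype(np.int64)
    counts = np.concatenate([pos[::-1], pos])
    return Autocorrelogram(lag_edges=edges, counts=counts)


def build_record(
    train: SpikeTrain,
    template: WaveformTemplate,
    isi_bin_ms: float = 1.0,
    isi_max_ms: float = 100.0,
    acg_bin_ms: float = 1.0,
    acg_window_ms: float = 50.0,
    label: str | None = None,
    metadata: dict | None = None,
) -> NeuronRecord:
    """Assemble a NeuronRecord, computing ISI histogram and ACG from the train."""
    return NeuronRecord(
        unit_id=train.unit_id,
        spike_train=train,
        template=template,
        isi=compute_isi_histogram(train, isi_bin_ms, isi_max_ms),
        acg=compute_autocorrelogram(train, acg_bin_ms, acg_window_ms),
        label=label,
        metadata=metadata or {},
    )


def _uniform_bin_count(extent: float, width: float, name: str) -> int:
    ratio = extent / width
    n = int(round(ratio))
    if extent <= 0 or n < 1 or abs(ratio - n) > 1e-9:
        raise ValueError(f"{name} must be a positive multiple of bin_width_ms")
    return n
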