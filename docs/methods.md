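# Methods

## Feature extraction

Spike times are kept in seconds internally; milliseconds appear only at the
feature boundary. All histograms use half-open bins `[lo, hi)` with the left
edge inclusive. The ISI histogram bins consecutive-spike intervals with 1 ms
bins over [0, 100] ms by default and discards intervals beyond the range, so
`sum(counts) = n_spikes − 1` exactly whenever the range covers every
interval. The autocorrelogram counts all ordered spike pairs with |Δt| inside
a ±50 ms window (1 ms bins), excluding self-pairs; positive lags are binned
half-open and the negative side is the exact mirror `(lo, hi]`, which is the
only convention under which the histogram is symmetric even when a spike-time
difference lands exactly on a bin edge. Waveform templates are the
elementwise mean of aligned snippets; the extremum ("peak") channel is the
channel of maximal peak-to-trough amplitude, ties resolved to the lowest
index, and the alignment point is the most negative sample (trough). The
default snippet window is 1 ms before and 2 ms after the trough. The
recording literature does not pin these binnings down; all are exposed in
the function signatures and the run config.

## Rendering

Feature images must be byte-identical across platforms and runs, because the
downstream embedding is deterministic and cached by content hash. We
therefore rasterize polylines directly into a uint8 grid — no anti-aliasing,
no text, no axes — rather than going through a plotting library whose output
depends on fonts and backends. Per-image min–max normalization maps the
feature to the full plotting area (margin 8 px in a 224×224 image; larger
values at smaller raster rows); a fixed-scale mode exists for comparable
amplitudes. A flat or empty feature renders as a mid-height baseline with a
warning flag rather than an error. Composite panels concatenate
waveform/ISI/ACG side by side and resize with box (area-average)
resampling, which is deterministic and, unlike nearest-neighbour
subsampling, does not alias thin traces away. The default palette is the
blue/orange/green convention spike toolkits use for the three panels.

## Embedding

Two backends sit behind one frozen-encoder interface. The
`mock_projection` backend converts the image to grayscale, block-averages it
to a 32×32 grid, removes the mean (background invariance), multiplies by a
fixed seeded Gaussian matrix, and L2-normalizes — a
Johnson–Lindenstrauss-style projection of the blurred pixel vector that is
deterministic, download-free, and preserves relative image similarity. The
`pretrained_vl` backend is the registered interface for a frozen CLIP/SigLIP
image tower; without locally available weights it fails with an explicit
"weights unavailable" error directing the caller to mock mode. L2
normalization happens inside the embedding module, so cosine similarity is
a dot product everywhere downstream. A raw time-series baseline
(peak-channel waveform, ISI counts, ACG counts, each z-scored, concatenated,
L2-normalized) bypasses the image pathway for comparison.

## Few-shot prototype classification

Class prototypes are the arithmetic mean of the K support embeddings,
renormalized to unit length (degenerate zero-norm means raise an error
naming the class). Query probabilities are `softmax(cos / T)` with default
temperature T = 1; the `Unknown` label is assigned when the top probability
falls below the rejection threshold (default 0.5 for single-unit
classification; the evaluation harness uses 0 so accuracy measures pure
prototype assignment). Exact probability ties are broken lexicographically
by label with an explicit tie flag. The evaluation protocol samples K
supports per class without replacement, classifies every remaining labeled
record, and repeats over five episode seeds; everything is reproducible
from one base seed. A random-forest-on-embeddings benchmark with a
stratified held-out split (default 5%) is provided as the non-prototype
comparison.

## Tracking decoder

Detection thresholds each channel at −k·MAD/0.6745 (robust Gaussian noise
estimate, default k = 5), finds peaks with a refractory spacing (1 ms), and
merges crossings across channels within the refractory window to the
largest-amplitude channel; events whose window is clipped by the stream edge
are skipped. The feature vector concatenates snippets from the n nearest
channels to the extremum (default 4, distance-then-id order), the
extremum-channel snippet, and the extremum's coordinates standardized by
the training-set mean and scale; all features are z-scored with training
statistics. The model is a two-hidden-layer perceptron (256, 64, ReLU,
softmax) trained with categorical cross-entropy at a fixed seed — the
smallest model family adequate for a flat feature vector; architecture,
window, and neighborhood are config. Noise-class exemplars come from
random stream segments away from true events (sorter-rejected clusters can
be passed the same way). Tracking metrics match events to ground truth
greedily by nearest time within 0.5 ms; unmatched truth events are misses
and unmatched predictions false positives.

## Similarity matching

The online network computes `y = M⁻¹ W x` and updates
`W ← W + η (y xᵀ − W)`, `M ← M + η (y yᵀ − M)` with M symmetrized each
step — the canonical online similarity-matching scheme consistent with a
Hebbian feedforward / anti-Hebbian lateral description. W is initialized
as small seeded Gaussian noise and M as the identity so the lateral system
is solvable from step 0; η = 0 freezes the state exactly. The default
schedule is constant η = 1e-3 (a 1/t decay is available); on a 10-D
anisotropic Gaussian stream with a 10× spectral gap the learned subspace
aligns with the top-2 principal subspace to error < 1e-3 within 5000
steps. Activity matrices are centered before streaming by default: raw
spike counts carry a large mean-rate component, and without centering the
network tracks the uncentered second moment rather than the covariance.
Binned activity uses 100 ms bins by default and pools inhibitory subtypes
(SST with non-SST GABAergic) into one group, reflecting the small unit
counts of chronic recordings. Trajectory smoothing convolves each output
dimension with a discrete Gaussian kernel normalized to sum 1, truncated at
±4σ, with reflect padding — fixed so smoothed trajectories are
byte-reproducible. The alignment diagnostic is
`1 − ‖Uᵀ V‖²_F / d_out` between orthonormal bases of the learned row space
of M⁻¹W and the top principal subspace of the (centered) activity.

## Synthetic data

The generators are pure functions of config + seed. Waveforms are a
two-lobe kernel — a negative Gaussian trough whose FWHM is the archetype's
trough width, plus a broader positive afterhyperpolarization lobe displaced
by the peak-to-trough interval — which is the minimal family expressing the
broad-and-bursty (pyramidal) versus narrow-and-fast (fast-spiking
GABAergic) distinction, with SST, juxtacellular, and axo-axonic archetypes
in between. Spike trains are gamma renewal processes with a hard refractory
floor and an optional burst-doublet mechanism whose extra spikes are
compensated in the base rate so the total rate matches the nominal rate in
expectation. Populations jitter archetype parameters multiplicatively:
±8% at the "separable" level (trough-width ranges of the default
archetypes stay disjoint) and ±35% at "hard" (ranges overlap). Recordings
place each unit's kernel as a spatially decaying footprint
(exp(−distance/λ), λ = 25 µm — a typical extracellular decay scale) on
white noise, with optional linear amplitude drift; latent sessions mix
Gaussian-smoothed unit-variance latents through a positive full-rank
loading into rates around 10 Hz and Poisson-sample counts.

What the generators do *not* emulate: electrode drift in position,
correlated or non-stationary noise, spike collisions and overlap, bursts
with amplitude attenuation, real ISI/ACG fine structure, and the
between-laboratory heterogeneity of real labeled datasets. Passing tests
therefore demonstrate the correctness and internal consistency of the
pipeline under controlled separation and drift, not field performance on
real opto-tagged data, which additionally depends on the choice of
pretrained encoder.

## Problem sizes and numerical choices

The test suite and the reproduction script use desk-scale conditions chosen
to exercise every code path: 4 cell types × 20 units for few-shot recovery
(5 episode seeds, K up to 8), a 16-channel, 60 s, 5-unit recording at
10 kHz (SNR 120 µV amplitude over 8 µV noise, 10% amplitude drift on the
second session) for tracking, and 5000 steps of 10-D input for subspace
recovery. Embedding dimension defaults to 64 for the mock backend.
Degenerate inputs (empty trains, all-zero features, flat images,
zero-variance segments, antipodal supports, singular lateral systems) are
handled by explicit flags or errors as documented on each function.

## Design decisions that were genuinely open

- Prototype construction is mean-then-renormalize; cosine is the
  similarity throughout (Euclidean distance to prototypes would be an easy
  config extension but is not the default).
- The image panel embedded for classification is the three-modality
  composite (waveform + ISI + ACG); single-modality layouts are config.
- The Unknown-rejection threshold and softmax temperature have no
  canonical values; both are exposed and default to 0.5 / 1.0.
- The evaluation harness reports accuracy with rejection disabled, so
  headline numbers measure the prototype geometry rather than the
  threshold choice.
- Noise training exemplars default to random segments; nothing in the
  decoder assumes they came from a sorter's rejected clusters.

## Known limitations

Images are compared only through the mock projection unless pretrained
weights are supplied; absolute accuracies on synthetic data say nothing
about any particular pretrained checkpoint. The decoder assumes the probe
geometry is fixed across sessions and models drift only as amplitude
scaling. The similarity-matching network recovers a linear subspace; it
will not untangle curved manifolds. Proportion plausibility is a pure
range check against a user-editable table and carries no uncertainty
quantification on small cohorts.
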