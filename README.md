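# spikesight

Cell-type inference and chronic unit tracking from extracellular
electrophysiology.

Extracellular recordings (Neuropixels, flexible arrays) resolve hundreds of
single units but say nothing directly about their molecular cell type, and
spike-sorted unit identities do not survive across recording days.
`spikesight` addresses both problems with a small, fully deterministic
pipeline:

1. **Per-unit features.** Each sorted unit is summarized by its trough-aligned
   waveform template, inter-spike-interval (ISI) histogram, and
   autocorrelogram (ACG) — the classic separators of broad-waveform, slow,
   bursty excitatory (pyramidal) cells from narrow-waveform, fast-spiking
   GABAergic interneurons.
2. **Few-shot cell typing.** Features are rendered as standardized,
   byte-deterministic images and embedded with a *frozen* image encoder
   (no training or fine-tuning anywhere). With K labeled examples per class,
   a unit-norm class prototype `p_c = mean(z_1..z_K)/‖·‖` is formed, and a
   query embedding `z_q` is scored by cosine similarity, passed through a
   temperature softmax `P(c|q) = softmax(zᵀ p_c / T)`, and assigned the
   argmax class — or `Unknown` when the top probability falls below a
   rejection threshold. A pluggable backend registry supports a pretrained
   vision-language tower and a deterministic mock projection encoder that
   makes the whole pipeline testable offline.
3. **Chronic tracking decoder.** A multilayer perceptron with one output per
   day-1 unit plus a reserved `noise` class, trained with categorical
   cross-entropy on multimodal spike features (nearest-channel snippets,
   extremum-channel snippet, standardized extremum coordinates), assigns
   every detected spike in later sessions to a day-1 identity without
   re-sorting.
4. **Population manifolds.** An online similarity-matching network
   (`y = M⁻¹Wx`; Hebbian `W ← W + η(yxᵀ − W)`, anti-Hebbian
   `M ← M + η(yyᵀ − M)`) streams binned population activity into
   low-dimensional, Gaussian-smoothed trajectories, converging to the
   principal subspace of the input covariance.
5. **Plausibility rules.** Inferred cell-type proportions are range-checked
   against an editable reference table (shipped: cortical SST interneurons,
   4–9%), and label consistency across sessions is quantified.

Seeded synthetic generators (archetyped neurons, multi-channel recordings
with ground truth, latent-dynamics sessions) provide the package's
download-free test substrate.

## Worked example

```bash
python examples/02_fewshot_classification.py
```

```
K-shot prototype classification (4 classes, chance = 25%):
  K=1: accuracy  86.1% +/- 6.1 over 5 seeds
  K=2: accuracy  93.3% +/- 5.2 over 5 seeds
  K=4: accuracy  94.4% +/- 4.9 over 5 seeds
  K=8: accuracy  99.6% +/- 0.8 over 5 seeds
confusion matrix at K=8 (rows = true, cols = predicted):
  classes: ('GABA_nonSST', 'Juxtacellular', 'Pyramidal', 'SST')
[[12  0  0  0]
 [ 0 12  0  0]
 [ 0  0 12  0]
 [ 0  0  0 12]]
```

Accuracy rises with the number of support examples per class and, on the
separable synthetic population, reaches a clean diagonal confusion matrix at
K=8 — the prototype classifier recovers each archetype from eight labeled
examples with no learned weights beyond the frozen encoder. The other
examples are one script per capability:

- `examples/01_spike_features.py` — feature extraction and its invariants,
- `examples/03_unit_tracking.py` — day-1 decoder on a 10%-amplitude-drifted
  second session (prints detection 0.965 / classification 0.984),
- `examples/04_population_manifold.py` — similarity-matching trajectories
  (subspace alignment error 0.022 vs batch PCA),
- `examples/05_plausibility_report.py` — proportion verdicts and 98%
  cross-session agreement on a cortical-like cohort.

A thin CLI wraps the same functions:
`spikesight simulate | classify | evaluate | manifold | report | pipeline`.

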