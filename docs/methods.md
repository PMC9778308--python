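# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `eegfst`, and what the synthetic-data suite
does and does not establish.

## Signal model and features

Trials are multichannel EEG matrices (channels × samples) at a fixed
sampling rate, with an optional pre-stimulus baseline prefix.  The native
archive geometry is the preprocessed-DEAP layout: 40 trials × 40 channels
(first 32 EEG) × 8064 samples at 128 Hz, 63 s per trial of which the first
3 s are baseline; labels are valence/arousal/dominance/liking ratings on a
1–9 scale, binarized high/low at a strict threshold of 5 (the threshold is
a parameter; 5 is the scale midpoint).  A 62-channel, 3-class SEED-like
dialect is also supported.

**Band decomposition.**  Five Butterworth band-passes at the classical
rhythm edges (1–4, 4–8, 8–13, 13–30, 30–50 Hz).  Design choices:

* order 3, applied forward–backward (`sosfiltfilt`), i.e. zero phase.  The
  order/phase convention is otherwise open; zero-phase filtering keeps
  segment boundaries aligned across bands, which matters because slices
  from different bands are stacked into the same tensor cell.  The
  effective magnitude response is therefore the squared order-3 response;
  each design is validated numerically (≥ 0.9 gain at the band's geometric
  centre, ≤ 0.1 at neighbouring centres).
* the δ low edge stays at 1 Hz even though preprocessed DEAP recordings
  are 4–45 Hz filtered; on such input the δ channel is close to empty.

**Segmentation.**  Non-overlapping 0.5-s windows (64 samples at 128 Hz);
a 63-s trial gives 126 windows, 120 after skipping the 3-s baseline.
Trailing partial windows are discarded so every window has exactly N
samples, as the spectral estimate requires a fixed N.

**Differential entropy.**  H = ½ ln(2πe σ̂²) nats with σ̂² = Σx²/N.  Two
variance conventions are exposed: the default subtracts the window mean
first (band-passed EEG is zero-mean in expectation, and mean removal makes
the feature invariant to residual DC); `zero_mean=True` uses the raw
energy.  The spectral route ½ log P + ½ log(2πe/N), with P the DFT energy
spectrum over the window, is algebraically identical (Parseval) and serves
as a numerical cross-check, not as a second feature.  Natural logarithms
throughout.  A zero-variance window maps to −inf with a warning.

**Gaussianity audit.**  The DE closed form assumes Gaussian windows.  The
audit applies a Kolmogorov–Smirnov test per window against a normal law
with moment-estimated mean and standard deviation (the estimated-parameter
form; using the segment's own moments makes the standard KS p-value
conservative, which only strengthens a ">90 % pass" style conclusion) and
reports the fraction not rejected at a significance level α (default 0.05).

**Baseline correction.**  Per band and channel, corrected_t = feature_t −
mean(base_1..6): the mean DE of the six baseline windows.  Correction uses
uncorrected DE on both sides and is applied to every emotional window of
the same trial.

**4D assembly.**  Channel values are scattered onto an h×w scalp grid;
cells without an electrode are structurally zero.  Bundled grids: DEAP-32
and SEED-62 on the compact 8×9 grid, SEED-62 on a sparse 19×19 grid, all
following the 10–20 projection and overridable by user CSV files.  Band
grids are stacked (h×w×a) and 2T consecutive slices form one sample.
2T = 6 (3 s of context) by default: a 60-s emotional portion then yields
20 samples per trial, a balance between temporal context and sample count.
Samples never straddle trials; remainder slices are dropped; each sample
inherits its trial's label.

## Classifier

Per time slice, a CNN with shared weights across slices: 1×1 conv (64
maps) → 3×3 conv (128) → 3×3 depthwise conv → separable conv (3×3
depthwise + 1×1 pointwise, 256 maps) → 2×2/stride-2 max pool → 512-unit
dense.  Every convolution uses zero ("same") padding, batch normalization
and ReLU.  Open details fixed here: batch normalization as the
"normalization" operation; depthwise multiplier 1; 256 pointwise maps;
batch norm + ReLU after the dense layer as well (a linear layer without
normalization can die — all ReLU units inactive for every input — which
silences every upstream gradient permanently; normalizing the
pre-activations makes that state unreachable); pooling after the separable
block, with odd spatial extents padded by −inf so the pool covers the full
map.  All
widths are configurable; `CNNConfig.reduced()` is the half-width variant
(32/64/128 maps, 256 dense units) used for desk-scale experiments.

The slice embeddings Q ∈ R^{512×2T} feed an ON-LSTM with 128 units.  Six
gates (forget, input, output, candidate, master-forget, master-input) each
have their own input and recurrent weights.  The master gates are
cumulative sums of softmax outputs — f̃ non-decreasing ending at 1, ĩ
non-increasing starting at 1 — and ω = f̃∘ĩ marks the overlap.  Two cell
updates are implemented:

* `as_printed` (default): c_t = ω∘(f∘c_{t−1} + ĩ∘ĉ) + (f̃−ω)∘c_{t−1} + (ĩ−ω)∘ĉ
* `canonical`: the overlap term uses the standard gates, ω∘(f∘c_{t−1} + i∘ĉ),
  as in the original ordered-neuron formulation; clamping both master
  gates to 1 then recovers the standard LSTM update exactly (asserted
  numerically).

A chunk factor (default 1) lets the master gates act at resolution
d/chunk, expanded by repetition, as published ordered-neuron models do.
The final hidden state feeds an affine softmax head.

**Training.**  Adam (β₁ 0.9, β₂ 0.999), learning rate 0.003, batch 120,
100 epochs, categorical cross-entropy — the full-scale recipe; desk-scale
runs use 20 epochs with the half-width model.  Weight init: He-normal for
convolutions and dense layers, Xavier-uniform for recurrent weights,
forget-gate bias 1.  The engine is an in-package numpy reverse-mode
autodiff (float32); backward frees each node's gradient, closure and
parent links as the sweep proceeds, bounding peak memory near the size of
one forward graph (≈ 1 GB at batch 120).  Every operation's gradient is
checked against central finite differences (in float64) in the tests.

**Cross-validation.**  Folds partition *trials*, not samples, so all
windows of a held-out trial are unseen at training time; group sizes
differ by at most one; folds are unstratified random partitions.  One
fresh model per fold.  Reported: per-fold accuracy, mean, sample standard
deviation (ddof = 1), pooled confusion matrix, per-class one-vs-rest
accuracy, precision, recall, F1 (NaN for classes absent from both label
lists).  Folds whose training split is single-class are skipped with a
warning.  All randomness derives from one seed via spawned seed sequences;
equal seeds give bit-identical folds and metrics.

## Synthetic data

The generator emulates the preprocessed-DEAP geometry exactly (shapes,
128 Hz, 63-s trials, 3-s baseline, 32 EEG + 8 filler channels of white
noise).  Each EEG channel is a sum of five independent Gaussian processes
band-limited to the rhythm bands — white noise shaped in the frequency
domain (out-of-band DFT coefficients zeroed, exact rescaling to the target
variance), deliberately *not* the analysis Butterworth filters, so
generator and analyzer stay independent — plus a 1/f pink background
(default std 0.5, low cutoff 0.5 Hz).  Base band variances decline gently
across bands (1.0, 0.8, 0.6, 0.4, 0.2), a caricature of the 1/f shape of
resting spectra.  Emotion classes act only through variance multipliers ρ
on designated (band, channel) pairs during the emotional portion; the
baseline prefix always uses base variances.  A multiplier ρ therefore
shifts baseline-corrected DE on affected cells by ≈ ½ ln ρ nats (slightly
less where the pink background dilutes the band), which is the
ground-truth effect the pipeline must recover.  Default root seed
20221830; one generator drives all randomness, so equal specs give
identical archives.

What the synthetic suite shows: that the implementation recovers injected
band-power class structure through the full pipeline at the stated sizes,
and that shuffled labels stay at chance (trial-level folds leak nothing).
What it does not show: performance on real EEG — there is no volume
conduction, no artifacts, no non-stationarity, no inter-subject
variability, and the class effect is far cleaner than real affective
modulation.

## Problem sizes of the shipped experiments

The acceptance run uses 20 trials per class (the DEAP per-subject trial
count split over two classes), ρ = 6 on β and γ at eight electrodes, the
half-width model, 20 epochs, 5 folds.  The label-shuffled control trains
for 2 epochs: with trial-level held-out folds, shuffled labels cannot
generalize at any training length, so the chance-level property is
independent of the schedule and a short one suffices.

## Known limitations

* The numpy engine targets this architecture; it implements only stride-1
  same-padded convolutions and 2×2/2 pooling, and is CPU-only.
* The exact layer recipe behind any particular published parameter/FLOP
  total is not recoverable from width specifications alone; parameter and
  FLOP counts here are exact for the configuration given to
  `count_parameters`.
* Per-subject protocols (one model per subject) are looped by the caller
  or CLI; no cross-subject transfer protocol is provided.
* The 19×19 sparse grid is supported as a layout, but all shipped
  experiments use the compact 8×9 grid.
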