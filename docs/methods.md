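# Methods

This note documents the models, procedures and numerical choices behind
`szdetect`: what each stage assumes, which parameters matter, and what the
synthetic benchmark does and does not demonstrate.

## Problem setting

Acute pharmacological seizure models (GABA_A antagonists such as picrotoxin,
potassium-channel blockers such as 4-aminopyridine) produce recordings in
which brief epileptiform discharges — 7 ms to several seconds — are embedded
in hours of non-seizure activity. The detection task is end-to-end: raw
multichannel signal in, event intervals out, with no filtering or feature
extraction. Scalp EEG enters the same pipeline after linear-interpolation
upsampling to an invasive-style rate and a fixed amplitude normalization.

All intervals are 0-based half-open `[start, end)` sample ranges; seconds
appear only at I/O boundaries.

## Synthetic data generator

The generator emulates the statistical structure of laminar-probe LFP and
scalp-EEG seizure data so the whole framework is testable without any
recordings:

- **Background**: 1/f-weighted Gaussian noise (FFT-domain `1/sqrt(f)`
  amplitude weighting, DC removed), normalized to zero mean and exactly unit
  SD per channel. All amplitudes in the package are therefore expressed in
  background-SD units, and `snr` means peak event amplitude in those units.
- **`ptx_burst`**: a dense train of biphasic sharp transients (~3 ms wide,
  ~4 ms period with jitter) with abrupt onset and offset. Two properties are
  deliberate: the inter-spike period is shorter than the 5 ms analysis
  window, and the envelope is flat — so *every* window inside an annotated
  interval contains discharge activity and the labels are faithful at the
  granularity the classifier operates on. An envelope that decays to zero
  inside the annotation would inject label noise (near-silent "seizure"
  windows) and measurably drags the decision boundary into background
  territory.
- **`fourap_spiking`**: a dense tonic-like spiking phase over the first half
  of the event followed by fixed-period (~25 Hz) spikes. The sparse phase
  genuinely contains inter-spike silence; windows there are harder, which is
  the point of the morphology.
- **`eeg_like`**: rhythmic ~3 Hz spike-and-wave for low-rate scalp-style
  scenarios, plus occasional isolated single-channel high-amplitude
  artifacts in the background (muscle-artifact stand-ins).
- **Depth profile**: each event template is scaled per channel by a smooth
  gain gradient (|gain| 0.4–1.2) with a polarity flip mid-array, mimicking
  the dendrite–soma–dendrite reversal seen along a laminar probe. Channels
  are correlated but distinguishable, which is what gives multichannel
  attention something to exploit.

Events are placed left to right with gaps drawn uniformly from the
configured gap range; leftover time becomes a trailing non-seizure interval,
and the annotations tile the recording exactly. Everything is reproducible
bit-for-bit from the scenario seed.

What the generator does **not** model: biophysical waveform realism,
state-dependent background (sleep/anesthesia depth), electrode drift,
line noise, or correlated noise across channels. Passing the synthetic
benchmark therefore demonstrates that the pipeline's machinery works and
that its claimed invariances hold — not that the trained tiny model would
transfer to real tissue.

## Augmentation

Window length is 100 samples (5 ms at 20 kHz). Three strategies:

- **Sequential**: every stride-spaced window of every segment; stride 1
  inside seizure segments, 50 inside non-seizure segments (defaults).
- **Random contiguous**: a requested number of windows per class, start
  positions uniform over the union of valid positions (segments weighted by
  their number of valid starts).
- **Random non-contiguous**: hybrid positives splicing `m ~ U{1..39}`
  non-seizure columns in front of `100 − m` seizure columns. Both blocks are
  contiguous runs, and the same time columns are taken across all channels,
  preserving cross-channel alignment — the classifier consumes channels as
  joint tokens, so per-channel independent splicing would destroy exactly
  the structure attention uses. The non-seizure block precedes the seizure
  block; `m` is recorded in provenance so alternative orders are testable.
- An optional **boundary pass** emits windows straddling seizure onsets,
  labeled positive only when they contain at least 61 of 100 seizure
  columns, i.e. the complement of the hybrid `m < 40` rule.

Class balance is the caller's responsibility; the end-to-end pipeline
targets ~20 000 windows at a near-1:1 ratio by choosing sequential strides
adaptively (total valid positions / per-class budget).

## Classifier

A window of C channels × L samples is treated as **C tokens of L features**.

1. Input projection MLP1: one linear map `L -> d_model` applied to every
   channel row.
2. N identical post-norm Transformer encoder layers:
   `LayerNorm(x + MultiHead(x))`, then `LayerNorm(y + FFN(y))`, with
   per-head scaled dot-product attention `softmax(QK^T/sqrt(d_k))V` and a
   two-layer ReLU feed-forward of width `d_ff`.
3. Output projection MLP2: two linear layers with a ReLU bottleneck
   (`d_model -> 128 -> 2` at the full size).
4. Readout: token 0's logits (default) or the mean over token logits,
   then softmax.

The reference configuration is `d_model = 1024`, `N = 8`, `h = 8`
(`d_k = d_v = 128`), `d_ff = 1024`. The `tiny` preset (`d_model = 64`,
`N = 2`, `h = 4`, `d_ff = 64`, bottleneck 32) keeps the identical structure
at CPU scale and is what all bundled experiments train.

There is **no positional encoding**: the model is agnostic to channel count
and ordering. Consequences, all verified by tests: every encoder layer is
token-permutation equivariant; the class score is invariant under
permutation of non-readout channels (token-0 readout) or any channel
permutation (mean-pool readout); and any channel count ≥ 1 runs without
reconfiguration.

The network and its gradients are implemented directly in NumPy (float64),
with reverse-mode backward passes per layer verified against central
differences. The tensors are small — sequence length is the channel count —
so a hand-written implementation is fast enough and keeps the dependency
surface minimal.

Open design points settled here: MLP1 is a single linear map (no
nonlinearity); MLP2 uses a ReLU between its two layers; the token-0 readout
is the default, with mean-pool as a config option.

## Training

Adam (default betas) on cross-entropy, fixed epoch budget, no early
stopping; the checkpoint with the highest validation accuracy is returned.
Ties go to the **latest** tied epoch: with an easily separable validation
set, accuracy saturates early, and the first tied checkpoint is the least
converged model with the thinnest margins — measurably worse at background
rejection during continuous inference.

The validation split is random, stratified by label (largest-remainder
allocation so the overall fraction is exact), and fully seeded.

Reference hyperparameters: lr 1e-5, 100 epochs, batch 2048 — sized for the
full model on millions of windows. The desk-scale preset used by the
pipeline and tests: lr 3e-4, ≤ 20 epochs, batch 64.

**Channel-subset augmentation** (`channel_subsample_prob`, pipeline default
0.5): half the training batches see a random subset of 1/2/4/8 channels.
A model trained only on 16-token windows is near-perfect at 16 channels but
produces hundreds of false-positive events when run on 4- or 8-channel
recordings — a pure token-count distribution shift, since the background is
statistically identical on every channel. Subsampling batches during
training is this package's mechanism for making the channel-agnostic
property hold in calibration, not just in shape.

## Detection and evaluation

Inference slides a window every `step` samples (5–20; default 20, i.e. 1 ms
at 20 kHz) and flags starts with `p_seizure > 0.5` (argmax of the 2-class
softmax; ties negative). Each flagged start spans `[s, s+L)`; spans whose
silent gap is at most `merge_gap` samples (default 400 = 20 ms at 20 kHz,
the minimum in-vivo inter-seizure interval) are merged into one event. The
gap is measured between span end and next span start, so "400 samples"
means 400 unflagged samples of signal.

Scoring is event-level with **any-overlap matching**: a true seizure
interval touched by at least one detected event is a TP; untouched true
intervals are FNs; detected events touching no true interval are FPs. One
detection spanning two true events credits both; fragmented detections
inside one true event credit it once and create no FPs. Metrics:

    recall = TP/(TP+FN)   precision = TP/(TP+FP)
    F1 = 2PR/(P+R)        event accuracy = TP/(TP+FP+FN)

Event accuracy is a threat-score-like quantity without a true-negative
term; outputs label it `event_accuracy` to avoid confusion with sample
accuracy. Zero-denominator ratios are reported as NaN, never silently 0.
Aggregation over subjects reports mean and SD; population SD is the
default display and sample SD is always computed alongside.

## The bundled end-to-end benchmark

`szdetect.pipeline.run_e2e` (also `szdetect e2e` and
`scripts/acceptance.py`) fixes these study conditions: 16 channels, 20 kHz,
60 s per recording, 20 embedded `ptx_burst` events of 0.05–1.5 s at snr 6
with 0.5–2 s gaps; ~20 000 windows (sequential ~6000/class, random
contiguous 3000/class, 2000 hybrids); tiny preset, lr 3e-4, 20 epochs,
batch 64, channel-subset augmentation 0.5; detection at step 20 with merge
gap 400 on a held-out recording from the same scenario, then again with
channels subsampled to 1, 2, 4 and 8. One global seed fans out to per-stage
seeds via `SeedSequence`, so each stage is individually reproducible.

Typical behavior at these conditions: event-level F1 and recall at or near
100% with 16, 8 and 4 channels; 1–2 channel detection is markedly less
precise (isolated background windows on a single electrode carry much less
evidence), mirroring the qualitative degradation reported for low channel
counts at full scale. Problem sizes were chosen so the whole run completes
in a few minutes on one CPU core.

## Known limitations

- The NumPy training loop is single-threaded beyond BLAS; the full-size
  configuration (d_model 1024, N=8) is implemented and tested for shape
  and correctness but is not practical to train here.
- EDF support is read-only, via mne; the canonical container is HDF5.
- The any-overlap matching rule and the half-open gap convention are
  documented choices; alternative conventions (one-to-one matching,
  start-to-start gaps) would change FP/TP accounting on pathological cases.
- Synthetic waveforms are analytic stand-ins; no quantitative claim about
  real PTX/4-AP electrophysiology is made or tested.
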