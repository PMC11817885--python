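# Methods

This note records the models, conventions and numerical choices behind
the package, and what the synthetic tests do and do not establish.

## Problem and unit of analysis

The task is binary classification of resting-state EEG into
normal-sleep (NS) and sleep-deprived (SD) conditions. The unit of
classification is one 15 s, single-channel window (7500 samples at
500 Hz). Recordings are cut into non-overlapping, left-aligned windows;
a trailing remainder shorter than one window is discarded, and every
window inherits its recording's condition tag. No filtering, artifact
rejection or re-referencing is applied; a preprocessing hook exists but
defaults to the identity, because the protocol defines none.

## Tunable Q-factor wavelet transform

The decomposition is an iterated two-channel filter bank defined in the
frequency domain by `β = 2/(Q+1)` and `α = 1 − β/r`, with the
Daubechies transition response `θ(ω) = ½(1+cos ω)√(2−cos ω)`. Defaults
`Q = 2, r = 4, J = 12` give 13 sub-bands: 12 detail bands ordered high
frequency to low, then the final low-pass. Band ordering is frozen
because the 14-source feature layout depends on it.

Implementation choices:

* **Exact tight frame.** Filter weights are assigned per DFT bin with
  `h0² + h1² = 1` everywhere, so energy conservation and perfect
  reconstruction hold to machine precision (the test tolerance of
  1e−8 relative is conservative; observed error is ~1e−15).
* **Arbitrary lengths.** Child lengths preserve the parent's parity, so
  odd intermediate lengths need no special casing; the child Nyquist
  bin is zeroed on the low-pass side (the transition lands exactly on
  it), avoiding any double-mapped bin.
* **Coefficients, not reconstructions.** Features default to the
  sub-band coefficient sequences (the transform's native output). At
  the default parameters on 7500 samples the shortest band has 674
  coefficients, comfortably above the 169-sample texture block. A
  configuration switch substitutes full-length single-band
  reconstructions instead; layouts are identical.
* A depth request beyond what the signal length supports raises an
  error reporting the maximum feasible `J`.

## Melatonin-graph texture extractor

Each 169-sample sliding block (stride 1) is reshaped column-major into
a 13×13 matrix — `matrix(row, col) = block[(col−1)·13 + row]`, 1-based,
matching column-major array semantics; a row-major option exists. The
18 directed edges compare matrix entries under three kernels (signum,
upper ternary, lower ternary); the ternary threshold is half the sample
(n−1) standard deviation of the **whole input signal**, computed once
per source, because the threshold definition is written over the signal
rather than the block. Group `g` of six bits is read as a 6-bit code
with the first bit most significant; nine 64-bin histograms of raw
counts (normalisation is left to downstream standardisation; a
per-block normalisation option exists for variable-length inputs) form
the 576-vector.

The default edge table is a planar embedding of melatonin's heavy-atom
skeleton — 17 atoms and 18 bonds including both indole rings — on the
13×13 grid, constrained to place edge 3 at (13,10)→(11,12). It is a
faithful-topology layout, versioned and swappable via a JSON file
(`{edges, groups, name, version}`); every structural property of the
extractor (counts, bounds, conservation) is independent of the table.

One deliberate correction: reading group 3 with weights `2^{13−k}` for
bit positions k = 13..18 would produce non-integer codes; the package
uses `2^{18−k}`, which is the only choice consistent with each group
spanning the 64 possible 6-bit codes.

## Statistical descriptors

Twenty descriptors per signal version (signal and absolute value), 40
in total: min, max, mean, median, sample sd and variance, RMS, energy,
five wavelet-family entropies, skewness, kurtosis (raw fourth
standardised moment, not excess), median absolute deviation, and four
round-out descriptors — range, interquartile range, mean absolute
deviation, crest factor — chosen to complete the block of 20; they are
swappable without affecting any downstream stage. Entropy parameters
default to `ε = sd/2` of the version being described (reusing the
ternary-threshold convention) and norm exponent `p = 1.5`; both are
configuration keys since no canonical values exist. Degenerate inputs
return defined values (constant signal: zero spread, zero skewness and
kurtosis; all-zero signal: crest factor 0) rather than raising.

## Feature assembly and selection

Source order is frozen — raw first, then detail bands high→low, then
low-pass — and within each source the 576 texture counts precede the 40
descriptors: (576+40)×14 = 8624 columns, each with a manifest name
`source/extractor/descriptor`. Ablation flags drop the texture block,
the descriptor block, or only the ten entropy descriptors; the manifest
always matches the emitted layout.

Chi2 ranking min-max scales each feature, discretises it into 10
equal-width bins (bin count configurable; the scale makes the score
exactly invariant under positive affine maps) and computes the
chi-square statistic of the bin × class table with expected counts from
the marginals and empty bins dropped. Constant features score 0.

NCA feature weighting maximises the averaged leave-one-out
soft-neighbour objective `(1/n)Σᵢ Σ_{j≠i, yⱼ=yᵢ} p_ij − λΣ w²` with
`p_ij = softmax_j(−Σ_l w_l²|x_il − x_jl|)`, features z-scored
internally, λ defaulting to 1/n. The softmax is shift-stabilised, so
large initial distances (w = 1 in thousands of dimensions) cannot
underflow. The ascent uses L-BFGS-B; one objective evaluation at
n = 200 segments and 8624 features costs two BLAS passes over the
n²×d pairwise-difference tensor (~1.4 GB in float32, precomputed when
it fits a 2 GB cap, rebuilt chunk-wise otherwise). Because the top-256
*ranking* stabilises long before the objective meets its tolerance, the
pipeline configuration caps the solver at 60 iterations by default
(~1 min/channel on one CPU at the sizes above); `nca_rank` itself
defaults to 200 iterations and warns when the cap is hit, returning the
best iterate. A known property of this objective is that with λ = 1/n
and small samples it can fit noise (the leave-one-out term is itself an
in-sample quantity), so all-noise weights are only guaranteed to
collapse under a sufficiently strong penalty; selection robustness
comes from the Chi2 union rather than from NCA sparsity.

Top-k sets (ties broken stably towards the lower feature index) from
both rankings are united; the union size is bounded by [k, 2k], i.e.
[256, 512] at the default k.

## Classification and fusion

Per channel: stratified 10-fold cross-validation with a seeded shuffle
(the protocol does not state fold seeding; a fixed global seed makes
reports byte-reproducible), per-fold z-scoring fitted on the training
folds, Gaussian-kernel SVM with kernel scale σ = 20 applied to the
standardised features and box constraint C = 1. Out-of-fold predictions
form the channel's prediction vector. Accuracy, sensitivity,
specificity, precision and F1 come from the confusion counts with SD as
the positive class (configurable); zero-denominator metrics report 0
and are flagged.

Fusion sorts prediction vectors by accuracy (descending, stable) and
majority-votes the top-k pools for k = 3..n, yielding n−2 voted
vectors; even-pool ties go to the prediction of the most accurate
channel in the pool (deterministic and accuracy-weighted — the bare
mode leaves this open). The greedy step returns the most accurate of
all n + (n−2) candidates, ties resolved towards fewer channels, then
channel vectors over voted vectors. Both stages read the true labels by
construction, so fused figures are labelled selection-optimistic in
every report; they measure the protocol, not held-out generalisation.

The optimism is not confined to the fusion stages. The protocol ranks
and selects features on the full labelled matrix *before* the 10-fold
cross-validation, so with thousands of candidate features and a few
hundred segments the selected noise features carry real in-sample
association and the cross-validated accuracy of a contrast-free
dataset lands well above chance (selection bias in the sense of
Ambroise & McLachlan). Segment-level fold assignment adds a second,
milder optimism: segments of one recording share slow structure and a
single label, so folds are not independent of the recordings they
exclude. Both effects are properties of the protocol being
implemented; the suite's null-calibration check runs the contrast-free
condition end-to-end and records the observed inflation. For honest
generalisation estimates, select features inside each training fold
and split by subject — both deliberate non-goals here, since the aim
is a faithful implementation of the published procedure.

## Synthetic generator

The generator emulates the study conditions — 500 Hz, 5-minute
recordings, 15 s windows, a within-subject NS/SD pair per subject —
at configurable channel counts. Each channel is a weighted common 1/f
source (RMS 6 µV, weights U(0.5, 1): spatial correlation), independent
1/f background (RMS 10 µV), plus band-filtered Gaussian oscillations:
slow band 1–8 Hz (RMS 3 µV under NS) and alpha 8–13 Hz (RMS 5 µV). The
class contrast is a single parameter, the SD/NS slow-band *power* ratio
(default 3, i.e. amplitude ×√3; ratio 1 = identical distributions).
Identical seeds give bit-identical output.

What it does not emulate: artifacts (blinks, muscle, line noise),
non-stationarity within a recording, realistic scalp topography,
subject-level spectral idiosyncrasies, or any texture-level (as opposed
to band-power) class difference. Passing the planted-signal tests
therefore shows the pipeline recovers a known spectral contrast
end-to-end and stays at chance under the null; it does not certify
performance on real recordings.

## Test problem sizes

The end-to-end checks run 5 subjects per class × 4 channels × 5 min
(200 aligned segments per channel) with the default 3× contrast and
with the null ratio 1 — sizes chosen so the full double pipeline
completes in minutes on a single CPU while keeping ≥10 segments per
class per fold. The brute-force oracle comparison uses 50 signals of
length 169–1000; reconstruction tests cover lengths {512, 1000, 7500}
and parameter triples {(1,3,4), (2,4,12), (3,5,8)}.

## Known limitations

* The published 61-channel headline accuracies are dataset-dependent
  and can only be reproduced against the original study recordings;
  nothing desk-scale asserts them.
* The exact 18-edge layout of the original figure is not recoverable
  from text; the default table is a faithful-topology stand-in and any
  exact table can be dropped in via JSON.
* Feature selection, vote ordering and greedy selection all see the
  full label vector before cross-validation — faithful to the
  protocol, but optimistic; treat fused accuracies accordingly.
* The EDF writer covers only the continuous 16-bit subset used for
  round-trip tests (1 s records, per-channel physical scaling).
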