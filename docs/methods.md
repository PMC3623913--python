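# Methods

## Problem and model

P300 spellers decode the character a user attends to on a 6×6 matrix
whose rows and columns flash in random order. Reducing the electrode
montage per user is valuable (setup time, comfort, hardware cost), but
requires a ranking of channels by their contribution to target/non-target
discrimination. This package implements a channel ranking built entirely
on *phase* measurements, motivated by the oscillatory account of
event-related potentials: target stimuli partially reset the phase of
ongoing oscillations in task-relevant cortical sources, so task-relevant
channels show inter-trial phase concentration after target flashes while
channels that merely mirror one another (homologous, shared-source) carry
redundant information.

### Circular statistics

With `φ_x(t)` the Hilbert (analytic-signal) phase of channel `x` on one
trial, `E_x = exp(jφ_x)`, and averages taken across the `n` trials of one
condition:

- `ITC_x(t) = |⟨E_x⟩|` — inter-trial coherence of one channel.
- `PLV_xy(t) = |⟨E_x Ē_y⟩|` — consistency of the phase *difference*;
  high for channels fed by a common source, task or no task.
- `PCV_xy(t) = |⟨E_x E_y⟩|` — consistency of the phase *sum*; high only
  when both phases are concentrated by the event, i.e. task-driven.
- `PLCV_xy(t) = PCV_xy(t) · (1 − PLV_xy(t))` — high for *heterologous*
  pairs that are *jointly concentrated*. The multiplicative form makes
  `PLCV_xx ≡ 0` exactly (a channel paired with itself has `PLV = 1`),
  which is the property the elimination step relies on.
- `TE_xy(t) = PLCV_xy^target(t) − PLCV_xy^nontarget(t)` — the target
  effect, each condition averaged over its own trial count.

All circular averaging is done on unit phasors, never on raw angles.

### Ranking (PLCV-RFE)

The pairwise similarity is `S_xy = max_t TE_xy(t)` over a post-stimulus
window (default the full 0–700 ms response). Each iteration over the
surviving set of `k` channels:

1. build a single-linkage hierarchy over `S` treated as distance and cut
   it into `k−1` classes — the unique 2-member class is the global
   minimum-`S` couple (asserted equivalent to the direct argmin in the
   tests; the implementation uses the argmin, with lexicographic
   tie-break, and logs the tree);
2. compute each couple member's task-relativity value
   `TRV_x = (1/(k−1)) Σ_{y≠x} S_xy` over the surviving set;
3. eliminate the lower-TRV member (ties drop the lower montage index)
   and prepend it to the rank list.

A duplicated or shared-source channel has `TE ≈ 0` with its twin, hence
minimal `S`, so redundant couples are found first, and the twin with less
support across the rest of the montage is discarded. Because TE is purely
pairwise, eliminating a channel cannot change the remaining entries of
`S`; the per-iteration "reconstruction" is therefore implemented as
subsetting, with a `recompute_similarity` flag that recomputes from
phases for fidelity checks (tested equal).

Rank lists from several runs/subjects are aggregated by scoring each
channel `n − position` within a list, z-scoring within the list, and
averaging across lists.

### Decoding and evaluation

A binary Fisher discriminant is trained on single-trial vectors of the
20 Hz stream (14 samples × selected channels, channel-major, no further
normalization; the 1:5 target:non-target imbalance is left as is). The
pooled within-class covariance gets an additive ridge
`λ = 10⁻⁶ · trace/d` because 448-dimensional features on a few thousand
trials are near-singular. Characters are decoded per block by summing
scores per stimulus code over the first `r` repetitions and intersecting
the argmax row (codes 1–6) with the argmax column (codes 7–12); argmax
ties resolve to the lowest code. The CRE curve retrains the FLDA for each
top-`n` channel subset of a rank list and decodes the held-out blocks at
every repetition count; the OCS at a given repetition count is the
smallest subset size attaining the row minimum. The default protocol
split is first half of blocks train, second half test.

## Preprocessing

0.1–40 Hz zero-phase Butterworth (order 5 per edge; the forward-backward
pass squares the magnitude response, and order 5 keeps 50 Hz ≥ 20 dB
down after both passes), decimation 1000→200 Hz for phase analysis and
200→20 Hz for classification (zero-phase FIR anti-aliasing), and 700 ms
post-onset epochs. The filtfilt reflect padding is stretched to three
time constants of the 0.1 Hz edge; scipy's default padding leaves
multi-second high-pass transients. Phases are computed on windows padded
by ±1 s cut from the continuous 200 Hz stream and cropped back after the
Hilbert transform, so FFT edge artifacts fall outside the analysis
window. (Whether the original recordings were phased per-epoch or
continuously is not specified anywhere we could rely on; the padded
route is an implementation choice and `analytic_phase` on bare epochs
remains available.)

## Synthetic sessions

The simulator emulates the recording protocol: 6×6 matrix, 12
intensifications of 100 ms + 75 ms blank per repetition in randomized
order, 15 repetitions per character block, 2.5 s blank before each
block, 80 blocks, 1000 Hz — giving the protocol's 14,400 trials
(2,400 target) after epoching.

Signal model, per source: a sinusoid whose instantaneous frequency
wanders slowly (low-passed Gaussian drift, σ = 0.3 Hz, cutoff 0.3 Hz —
pure sinusoids would make same-frequency PLV degenerate at 1), plus 1/f
background noise. Channels are `mixing @ sources` plus white sensor
noise. Defaults chosen as a plausible resting alpha regime: 16 channels
(32 available), one private source per channel spread over 8–13 Hz,
10 µV oscillation amplitude, 3 µV 1/f, 2 µV white noise.
`shared_source_mixing` builds montages with homologous pairs.

On each *target* flash, sources feeding the `relevant_channels`
(defaults: Cz, P7, P8, Oz) have their phase redrawn from
von Mises(μ=0, κ=5) at 50 ms latency, blended over a 50 ms raised
cosine, then free-run; κ=0 degenerates to a uniform redraw, i.e. no
target effect. The additive evoked variant (disabled by default) adds a
Gaussian bump (peak 300 ms, σ=60 ms) to relevant channels on target
trials.

What the simulator does *not* model: volume-conduction head geometry,
ocular/muscle artifacts, non-stationary background spectra,
subject-specific latency jitter. Passing tests therefore demonstrate the
algorithmic properties of the method under its own generative
assumptions, not clinical performance on recorded EEG.

## Problem sizes used in the test suite

Chosen so the whole suite runs in a few minutes on one CPU:

- protocol-count check: full 80-block session (≈35 s);
- parameter recovery: 50 seeded 10-block sessions, 16 channels, 4
  relevant, κ=5 — all 4 relevant channels must land in the top 4 ranks
  in ≥ 80 % of runs (10 blocks already gives stable TE estimates at the
  default noise level; the reference protocol ranks on 40 blocks);
- redundancy: 20 seeded 2-block, 8-channel sessions with one duplicated
  channel — the duplicate must be in the first identified couple every
  time;
- ITC physiology: 20 seeds of 2-block sessions; the non-target trial set
  is subsampled to the target count before differencing ITCs, since the
  mean resultant length is positively biased by ~n^(−1/2) and the 1:5
  imbalance would otherwise fake a gap on irrelevant channels.

## Numerical choices and degenerate inputs

- Metric values are clipped to [0, 1] against last-bit excursions; the
  self-pair `TE` is then zero to ≤ ~2×10⁻¹⁶.
- Similarity matrices are symmetrized (`(S+Sᵀ)/2`) and the diagonal
  zeroed; linkage input is shifted by the matrix minimum since TE may be
  negative and linkage expects non-negative distances (a common shift
  does not change the merge order).
- Min-pair ties: lexicographic; TRV ties: eliminate the lower montage
  index; decode argmax ties: lowest code. All deterministic.
- `k = 1` remaining channel: prepended without clustering. Degenerate
  tree cuts (exact ties) fall back to the direct minimum pair.
- All simulator randomness flows from one seed through
  `SeedSequence.spawn` (schedule, oscillators, 1/f, resets, sensor noise
  are independent streams); equal configs are bit-identical.

## Known limitations

- The event table uses seconds; sample indices are `round(onset × fs)`,
  so sub-sample onset jitter is quantized.
- The EDF writer quantizes to 16 bits over the per-channel range and
  zero-pads the last record; use the native HDF5 container for lossless
  round trips.
- FLDA is the only classifier; SWLDA/Bayesian LDA and
  information-transfer-rate metrics are out of scope, as are SVM-RFE and
  SSNR-based baselines.
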