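# Methods

This note documents the models and procedures implemented in `olfeeg`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Problem setting

Three-class staging of Alzheimer's disease (AD, amnestic MCI, healthy
control) from odor-evoked EEG epochs. The target recording geometry is a
small elderly cohort (tens of subjects, ~110 usable trials each), four
channels (Fp1, Fz, Cz, Pz) at 200 Hz, epochs of 2 s (400 samples), signals
already blink-cleaned and band-limited to 0.5–40 Hz upstream. The package
takes epoched trials as input; artifact removal and filtering are out of
scope.

## Tunable Q-factor wavelet transform (TQWT)

An over-complete discrete wavelet transform built from an iterated
two-channel filter bank defined directly in the DFT domain. With Q-factor
`Q` and redundancy `r`,

    β = 2/(Q+1),   α = 1 − β/r,

each stage scales the low-pass branch by `α` and the high-pass branch by
`β`, using the power-complementary transition window
`θ(ω) = ½(1+cos ω)√(2−cos ω)`. After `J` stages the transform yields `J+1`
bands; level-`j` detail has length `2·round(β α^(j−1) N / 2)` (round half to
even, so lengths are bit-reproducible), the final approximation
`2·round(α^J N / 2)`. The admissible depth is
`J_max = ⌊log(βN/8)/log(1/α)⌋` — the deepest high-pass band must keep a
nominal support of 8 samples.

Numerical choices:

* **FFT implementation with circular boundaries and unitary scaling.** The
  analysis is then an exact Parseval frame (`‖x‖² = Σ_bands ‖w_j‖²`, tested)
  and inversion is exact to machine precision (~1e−15 observed, 1e−10
  asserted).
* **Odd-length inputs** are zero-padded by one sample; the pad is recorded
  in the `SubbandSet` and dropped on inversion, so round-trips stay exact.
* **Redundancy defaults to r = 3**, the canonical choice in the TQWT
  literature; it is a config knob, not a claim about any particular study.
* Reported band **center frequencies** follow
  `f_j ≈ α^(j−1)(2−β)·fs/4`; the approximation band is assigned half the
  would-be next detail center so the sequence stays strictly decreasing.
  These are descriptive labels (verified empirically by energy-localization
  tests at ±1 band), not sharp passband edges.

## Wavelet coefficient mapping (TQWCM)

TQWT sub-bands are ragged. To form an image, every band is linearly
interpolated onto the trial's original time axis: sample `k` of a length-`L`
band sits at abscissa `k·(T−1)/(L−1)` on the target grid `0..T−1`
(endpoints aligned). This convention makes the mapping the identity for
full-length bands and exact to machine precision on constants and affine
ramps, which is the contract the tests pin down; interior band samples are
therefore treated as spanning the full epoch rather than being centered in
per-coefficient bins. Rows are stacked high→low frequency; applied per EEG
channel this yields a `(channels × (J+1) × N)` tensor.

Rows carry **raw signed coefficients** by default (phase information is
preserved for the CNN); a magnitude option exists, since either reading of a
"scalogram-like" image is defensible.

## Spatial features

**CSP.** Per-class covariances are computed from time-concatenated trials
(uncentered sample covariance — standard for band-passed EEG — trace-
normalized, no shrinkage). For each class `c` the one-vs-rest generalized
eigenproblem `C_c w = λ (C_c + C_rest) w` is solved; each sub-problem
contributes eigenvectors in alternating extremal order, the pool is
deduplicated at absolute cosine similarity > 0.95, and the first 4 filters
are kept. Features are raw average power `mean_t (wᵀx(t))²` (a log option
exists, off by default). The one-vs-rest scheme and the alternating/dedup
selection are this package's choices for extending a two-class method to
three classes; a pairwise scheme would be an equally defensible variant.

**Covariance tangent space (CMTS).** Per-trial covariances use the
closed-form oracle-approximating shrinkage (OAS) toward scaled identity,
`Ĉ = (1−ρ)S + ρ(tr S/d)I`; this is the package's reading of "orthogonalized
analytical shrinkage", the only established referent of that phrase in EEG
covariance practice (plain sample covariance is available). The tangent
reference is the affine-invariant (Karcher) mean, computed by the standard
fixed-point iteration (init: arithmetic mean; tol 1e−8 on the tangent
gradient norm; max 50 iterations). A trial maps to
`vec_√2(log(R^(−1/2) C R^(−1/2)))` — upper triangle, off-diagonals weighted
√2 — so the vector's Euclidean norm equals the affine-invariant Riemannian
distance δ(R, C) (tested to 1e−8). With d = 4 channels the vector has
d(d+1)/2 = 10 entries.

Both extractors are strict fit/transform objects and record the trial
indices seen during fitting, which the evaluation runner audits.

## Fusion classifier

Implemented as a compact numpy layer library with explicit backpropagation
(`olfeeg.nn`): depthwise/pointwise convolutions (FFT-based along time),
batch normalization, ELU, dropout, average pooling, layer norm, multi-head
self-attention, Adam. Gradients are verified against central finite
differences end-to-end in float64.

Architecture (defaults in `FusionConfig`):

* **CNN over the TQWCM image.** Block 1: depthwise time convolution, kernel
  (1, 64), padding (1, 32), one kernel per EEG channel → BN → ELU → avg-pool
  → pointwise 1×1 to 64 maps → BN → ELU → dropout 0.3. Block 2: the same
  depthwise-separable pattern with a (1, 16) kernel, width raised to 128 in
  the pointwise step. All kernels have height 1, so the band axis is never
  mixed; after global average pooling over time each band yields one
  128-vector, and the extractor is exactly band-permutation equivariant
  (tested). Temporal average pooling (input decimation ×2, then ×16 and ×2
  after the depthwise stages) condenses the time axis before the wide
  pointwise mixes; since the path ends in global average pooling and the
  discriminative signal here is band-resolved power and slow envelopes, the
  coarse temporal grid costs little information while keeping a pure-numpy
  training loop fast on one CPU core.
* **Tokens.** Three learned linear projections (CSP vector, CMTS vector,
  and one shared projection for the per-band 128-vectors) map features to a
  64-d embedding; a learned source-type embedding plus a learned band-index
  embedding are added (no sinusoidal positions: sources are unordered,
  bands are indexed). Token count = 2 + (J+1) — 12 tokens at the default
  J = 9.
* **Encoder and head.** Two pre-norm transformer layers (4 heads,
  feed-forward 4×, GELU), final layer norm, mean pooling over all tokens
  (no CLS token), then a 3-layer head 64→64→32→3 with ELU and dropout 0.5
  between linear layers. Encoder depth/width, activations and pooling are
  this package's defaults, declared here, all exposed in `FusionConfig`.

Training: unweighted cross-entropy (no class weighting or oversampling),
Adam at lr 0.001, batch 64, 50 epochs by default, dropout 0.3/0.5. All
randomness (init, shuffling, dropout) flows from explicit seeds; same seed ⇒
bit-identical weights on CPU. CSP/CMTS vectors and images are z-scored with
training-fold statistics before entering the model (toggleable) — raw
microvolt-scale powers destabilize training otherwise.

Epoch selection: the default protocol scores the **last epoch**. A
`selection='best'` mode also tracks held-out accuracy per epoch and reports
its maximum; it is flagged optimistic, because selecting on the test score
biases the estimate upward, and is never the default.

## Evaluation protocol

Leave-one-subject-out: one fold per subject, ordered by subject id. TQWCM
images and per-trial covariances are unsupervised per-trial transforms and
are computed once; everything supervised or population-dependent (CSP,
Karcher reference, scalers, the classifier) is refitted inside each fold on
training subjects only. Each test trial is classified and the subject
receives the modal label; **any** voting tie resolves to AD (the
deliberately sensitive choice for a screening context — this also covers
ties not involving AD). The fold structure is repeated (default 5
repetitions, seeds = root + repetition index) and metrics are reported as
mean ± s.d.

Metrics use the binary confusion-matrix formulas per class one-vs-rest —
accuracy (TP+TN)/(TP+TN+FP+FN), precision TP/(TP+FP), recall TP/(TP+FN), F1
the harmonic mean — macro-averaged by default (weighted averaging is an
option). Subject-level voted metrics are primary; trial-level accuracy is
logged per fold. The aggregated confusion matrix uses the consensus (modal,
tie→AD) vote per subject across repetitions so its row sums equal the
per-class subject counts. A leakage audit intersects every fitted
extractor's recorded training-trial ids with the fold's test indices and
reports the count (asserted zero in tests).

## Synthetic data generator

Each trial is a sum over the four classical rhythms (delta 0.5–4, theta
4–8, alpha 8–13, beta 13–30 Hz) of amplitude-modulated band-limited noise
carriers (raised-cosine spectral masks; envelopes `1 + 0.5 sin` at
0.3–1.2 Hz), with class-specific per-band gains, passed through a
class-specific orthogonal channel mixing applied to channels of unequal
base amplitude (this is what creates class-dependent spatial covariance),
plus `1/f` pink noise at a configurable SNR, scaled to ~10 µV. Subjects
within a class receive a mild log-normal jitter (σ = 0.08) on the band
gains so cross-subject generalization is non-trivial. All randomness
derives from one root seed via `SeedSequence.spawn`, one stream per subject.

Defaults mirror the target cohort: (15, 7, 13) subjects per class
(healthy/MCI/AD), 110 trials per subject (3,850 total — near a realistically
attrited 120-trial protocol), 4 channels, 200 Hz, 400-sample epochs, lemon
presented with probability 0.75 per trial. Default gains follow the EEG
slowing picture (AD: delta/theta up, alpha/beta down; healthy:
alpha-dominant); default SNR is 5 dB, reflecting the low single-trial SNR of
stimulus-locked EEG. Epoch length is configurable because a stimulus-locked
analysis window is a study-level choice.

A **validation preset** (`validation_study_config`) defines the canonical
scaled-down recovery study used by the acceptance checks: 12 subjects
(4/4/4), 40 trials each, exaggerated signatures (each class dominant in a
different rhythm, larger mixing rotations) at 20 dB SNR. At this size a
LOSO study (12 folds × 3 repetitions, 10 training epochs) runs in minutes
on one CPU; these sizes are the package's validation conditions, chosen to
keep a desktop run practical while leaving the qualitative conclusion
(near-perfect recovery vs. chance under label permutation) unambiguous.

What the synthetic validation shows: the pipeline recovers class structure
that is expressed as band-power and spatial-covariance differences, with no
leakage, and collapses to chance when subject labels are permuted. What it
does not show: performance on real olfactory EEG — real recordings have
artifacts, non-stationarities, inter-subject variability far beyond a
log-normal gain jitter, and class effects much subtler than the validation
preset; numbers obtained here do not transfer to any real cohort.

## Known limitations

* The numpy training loop is CPU-bound; it is sized for 4-channel,
  2-second epochs and small cohorts, not for high-density EEG.
* Multi-class CSP selection (one-vs-rest, alternating extremal, dedup) is
  one of several defensible schemes; filters are not unique under
  near-duplicate covariance structure.
* The Karcher mean iteration assumes well-conditioned covariances; with
  fewer samples than channels supply the OAS estimator (default) rather
  than the plain sample covariance.
* EDF support is deliberately minimal (plain EDF, int16, 1-s records) and
  meant for interchange and round-trip testing, not as a full EDF+ writer.
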