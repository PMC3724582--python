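# Methods

## Signal model

The generator treats surface EMG during a held facial gesture as an
amplitude-modulated band-limited Gaussian process: white Gaussian noise is
band-pass filtered to 30–450 Hz (4th-order Butterworth, applied
forward-backward), rescaled to unit RMS, multiplied by the gesture's
per-channel amplitude `a_{g,c}` and a deterministic within-trial envelope,
and corrupted by white sensor noise (std `noise_floor`, default 0.02 EMG
units against signatures of 0.1–1.1). The default envelope is **constant**:
only the held (active) 2-s portion of each gesture is modeled, onset and
offset transients being excluded from processing by design; a trapezoidal
envelope (15 % linear ramps) is available for sensitivity checks. Rest
periods are not generated.

Gesture identity lives entirely in the length-3 amplitude signature
(left temporalis, frontalis, right temporalis). This matches what the
discriminative time-domain features (MPV, MAV, RMS, IEMG, SSI) measure:
they are all amplitude statistics. The default signatures place jaw
gestures on the temporalis channels, brow/eye gestures on the frontalis
channel, and lateralize the unilateral gestures. One pair — G1 (mouth
opening) and G8 (bilateral smile) — is declared *confusable*: the dataset
generator anchors G8's signature to G1's at their base offset, so raising
the `class_separation` multiplier spreads every other class apart while the
G1/G8 contrast stays fixed (their **relative** contrast shrinks as
`1/class_separation`). This reproduces the characteristic G1↔G8 confusion
structure of facial-EMG interfaces, where the two gestures share a
signaling source.

What the generator does **not** emulate: motor-unit action potentials,
recruitment/firing-rate structure, fatigue, electrode lift or motion
artifacts, power-line interference, inter-trial drift, and any
envelope dynamics of real gesture execution. Consequently, passing tests
demonstrate that the pipeline recovers amplitude-coded classes under the
stated noise model — not that the specific accuracy figures transfer to
real recordings. On this synthetic model MAVS (adjacent-window MAV
differences) is almost pure estimator noise, so unlike on real signals it
carries almost no class information and its normalized MI with MAV is low
rather than ≈1; MV is likewise near zero mean by construction. The weak
features are weak for a structural reason, which is exactly what the
ranking stages need to be testable.

Determinism: every trial's RNG stream is keyed by
(seed, subject, gesture, trial) through `numpy.random.SeedSequence`, so
datasets are bit-identical across runs and platforms and any subset can be
regenerated independently.

## Preprocessing

Filtering is a 4th-order Butterworth band-pass applied with `sosfiltfilt`
(zero phase, so amplitude features see no group-delay shift; the effective
magnitude response is the prototype squared). The band is a parameter
(default 30–450 Hz). Filtering runs **per trial** — filtering the
concatenated signal would smear energy across trial boundaries — while
windowing runs on the **concatenated 10 s of active signal per gesture and
channel**, giving ⌊10000/256⌋ = 39 windows of 256 ms at the defaults; an
incomplete tail window is discarded (floor rule), and a signal shorter than
one window yields an empty segment list with a logged warning rather than
an error.

## Features

The nine per-window features follow their printed formulas exactly;
choices worth noting:

- **VAR** uses the population 1/N form, not 1/(N−1).
- **SSC** counts interior samples that are local **maxima** with
  `x_i − x_{i+1} ≥ ε` (ε default 0.02 EMG units). The conventional
  definition also counts minima; that variant is available as
  `ssc_both_extrema` but is off by default, keeping the asymmetric
  peak-only rule.
- **MAVS** is defined between adjacent windows, so 39 MAVs give 38
  differences; the series is padded back to 39 (policy `zero`, default, or
  `replicate`) so every feature contributes the same 390 rows per subject.
  The padding policy is this package's construction.
- Features are computed on the filtered signal.
- Identities `IEMG = N·MAV` and `SSI = N·RMS²` are enforced by tests as
  algebraic cross-checks.

Combinations concatenate the first k ranked single-feature sets
channel-major within feature (e.g. `[mpv_ch1, mpv_ch2, mpv_ch3, mav_ch1,
…]`), giving 3k columns.

## Mutual information and rankings

MI uses an equal-width histogram estimator (default 10 bins per variable
over its own range), in bits, with exact order-independent accumulation so
MI(A;B) equals MI(B;A) bit-for-bit. The estimator choice is the simplest
reproducible one; bin count is exposed. For the feature–feature matrix the
three channels of a feature are concatenated into one vector per subject
(not averaged), normalized MI = MI/√(H(A)H(B)) is reported, and subjects
are averaged. Degenerate normalizations are defined explicitly: both
entropies zero → 1, exactly one zero → 0, each with a warning. Raw MI
feeds mRMR; class relevance treats the gesture label as categorical (no
binning).

mRMR uses the canonical greedy incremental scheme (the set-level
max(D−R) is combinatorial): first the max-relevance feature, then
repeatedly the feature maximizing MI(f;C) − (1/|S|)Σ_{s∈S}MI(f;s). The
recorded per-prefix D and R follow the set definitions (R includes the
diagonal self-MI terms its double sum prescribes). Ties break
alphabetically. RA ranking sorts by mean test accuracy, ties alphabetical.

## Classifier

Neurons store exact sufficient statistics: the recursive mean and
covariance updates reproduce the batch population moments of the absorbed
samples to ~1e−9 relative (tested against a brute-force oracle), and the
basis is the eigendecomposition of that covariance (eigenvalues descending,
signs fixed so each vector's largest component is positive; a zero
covariance yields the standard basis). Widths are fixed at the initial
radius A₀ = 0.5 throughout — coverage adapts by rotation, not inflation —
which is meaningful because the pipeline min-max normalizes inputs to
[0,1] per dimension using training-set extrema (test values are not
clipped). Tentative updates are computed on copies and committed only on
coverage (ψ ≤ 0).

Two parts of the procedure are this package's own concretization, chosen
where the method leaves them open:

- **Merging**: after each neuron insertion, a same-class pair whose center
  distance is ≤ `merge_gamma` × (sum of mean widths) is pooled by exact
  moment pooling (counts, means and population covariances of the union),
  widths reset to A₀. Merging never increases the neuron count and is on
  by default.
- **Decision rule**: prediction returns the class of the minimum-ψ neuron
  (ψ is the network's only scoring quantity), ties to the
  earliest-created neuron. A nearest-center rule is the natural
  alternative; min-ψ uses the learned orientation and is the default.

## Experiment driver and evaluation

Per subject and feature: seeded shuffle, stratified 300/90 split (exact
30/9 per class on balanced sets — stratification guarantees every class
appears in training, which per-class neuron creation requires; a
non-stratified mode exists), min-max normalization, one-epoch training,
evaluation. Mean absolute error is defined as 100 − test accuracy.
Confusion matrices are row-stochastic percentages; per-gesture accuracy is
the diagonal. Split seeds derive deterministically from
(experiment seed, subject, feature label), so every result is a pure
function of the config; training time is measured but excluded from all
reproducibility contracts.

Problem sizes follow the study design throughout: 10 subjects, 10 gestures
× 39 windows × 3 channels (390 rows), 300/90 splits, combinations C2–C10
under both rankings. The full run completes in well under a minute on one
CPU. The `class_separation = 2.0` setting used in the recovery checks is
the "well-separated classes" condition under which amplitude features are
expected to exceed 95 % accuracy; the default 1.0 keeps the base
signatures, where accuracy lands in the high 80s to mid 90s with the
G1/G8 confusion dominating the errors.

## Known limitations

- Synthetic amplitudes are in arbitrary units; no calibration to real
  facial-EMG microvolt levels is attempted.
- The histogram MI estimator is biased upward for small samples; the
  independent-variables test budgets ≤ 0.05 bits for that bias at
  n = 10⁴, 10 bins.
- The VEBFNN result depends on sample order (any one-pass learner does);
  determinism is guaranteed only for a fixed shuffle seed.
- SVM / MLP baselines are intentionally out of scope; where a comparison
  is wanted, use established implementations directly on the exported
  feature CSVs.
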