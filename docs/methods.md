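# Methods

## Problem and model

The package classifies each short window of a meeting participant's
face-tracker output into one of three classes: *other* (0), *nodding* (1),
*speaking* (2). The underlying model is deliberately simple: nodding is a
quasi-periodic oscillation of the head-pitch angle, speaking a quasi-periodic
oscillation of the lip aperture, and everything else is background. A window
summary of time- and frequency-domain statistics feeds a random forest; no
temporal model (HMM, RNN) links adjacent windows.

## Signals

- `pose_Rx`: the pitch channel of the tracker's head-rotation estimate,
  radians. Copied verbatim — no smoothing or interpolation, and tracker
  confidence columns are ignored, since low-confidence frames carry the same
  label as their neighbors and the windowed statistics are robust to isolated
  glitches.
- `lip_62_66`: Euclidean distance in pixels between landmarks 62 and 66
  (0-based; the inner upper- and lower-lip midpoints). Raw pixel distance,
  not normalized by face size: within one seated session the face scale is
  nearly constant, and normalization would entangle the lip signal with head
  pose. This is a known limitation for cross-camera transfer.

## Windowing and labels

Windows are 32 frames wide with a 16-frame step (50 % overlap), aligned to
frame 0, half-open `[start, end)`; trailing partial windows are dropped
rather than padded, so every feature sees a full-length slice. 32 frames at
29.97 fps is ≈ 1.07 s — the scale of a single nod — which is why the same
width also serves as the nodding-duration mean in the generator.

Interval annotations rasterize onto frames with half-open membership
`start ≤ t < end` (no frame is counted by two touching intervals). Where a
nodding and a speaking interval overlap, nodding wins: the pipeline predicts
a single label per window, a deterministic rule is required, and giving the
rarer class priority preserves its scarce positives. The window label is the
majority frame code, ties broken nodding > speaking > other for the same
reason.

## Features

Per channel: 14 time-domain + 16 frequency-domain values; two channels give
the 60-vector. Numerical conventions, chosen once and pinned by oracle tests:

- moments are population moments (1/N); kurtosis is not excess-corrected;
- entropy is `Σ c·ln c` with `c_i = |s_i|/Σ|s_j|` and `0·ln 0 = 0` — computed
  on the absolute signal so it stays defined for signed rotation values, and
  left with its natural (non-negative-sum-of-negatives) sign;
- quartiles interpolate linearly at position `p·(N−1)`;
- the Burg estimator returns the prediction-polynomial coefficients
  `a_1..a_4` (with `a_0 = 1` implied), is not demeaned, and returns zeros for
  a constant slice instead of failing — silent stretches of a meeting must
  not abort extraction. The in-package lattice recursion agrees with an
  independent reference implementation to ≈ 1e-15 in tests;
- the spectrum is the magnitude of the DFT of the mean-subtracted slice,
  bins `1..width/2` (DC excluded so the peak-bin and weighted-mean features
  describe oscillation rate, not offset; Nyquist included), 16 bins for the
  default width;
- band energies average `s_i²` over three contiguous 1-based bands —
  (1,5), (6,10), (11,16) for 16 bins; for other window widths the bands are
  re-derived as a near-equal three-way split with remainder bins assigned to
  the trailing bands, keeping the sweep well-defined;
- the spectral power sum is divided by the sampling rate (frames/second) to
  give a density-like value;
- degenerate inputs (zero variance, all-zero spectrum) return 0 for AR
  coefficients, skewness, kurtosis, weighted mean frequency and correlation.

Cross-signal functions (signal magnitude area, Pearson correlation, angle to
a reference vector) require a signal triple and are excluded from the default
per-channel vector; they are available for multi-signal configurations.

## Classifier and evaluation

Random forest: 100 trees, Gini impurity, 7 candidate features per split
(⌊√60⌋; when `max_features` is unset it resolves to ⌊√n⌋ at fit time). The
pooled window set is balanced **once** by seeded downsampling to the
minority-class count before either CV split — balancing inside each fold
would change the test distribution fold to fold and make confusion matrices
incomparable. The 10-fold split is a plain seeded shuffle (stratification is
available behind a flag but off by default); LOPO forms one fold per
participant with train/test participant sets disjoint by construction.

Macro-average F1 is the unweighted mean over **all three** classes including
*other*. Metric aggregation is mean ± std over folds; the confusion matrix
pools all test predictions. 0/0 in precision/recall/F1 is defined as 0.

Every random stage draws its seed from one top-level integer through
`derive_seed(seed, stage) = (7919·seed + stage) mod 2³¹`, so an entire run is
reproducible from a single value.

The timeline export maps per-window predictions to seconds via the frame
rate and merges consecutive windows with the same non-*other* prediction into
one interval (first window start to last window end).

## Synthetic data: what it emulates and what it does not

The generator produces tracker-style sessions: a fixed 68-point template
face with per-frame Gaussian landmark jitter (sd 0.5 px), rotation jitter
(sd 0.01 rad), and non-overlapping behavior events separated by exponential
gaps (mean 6 s), each speaking with probability 0.5. Event durations are
gamma-distributed with shape 4 — strictly positive and right-skewed like real
behavior bouts — with means fixed at 4.01 s (speaking) and 1.06 s (nodding),
the average bout lengths observed in annotated meetings. During a nod the
pitch channel carries `A·sin(2π f t)` under a Hann envelope with
per-participant `A ~ U(0.05, 0.30) rad` and `f ~ U(1, 3) Hz`; during speech
the lip aperture follows `baseline + 4·|sin(2π·4·t)| px` and landmarks 62/66
are placed to realize that distance exactly. Noise is clipped (rotation at
3 sd, lip-distance jitter at 2 sd) so that excursions beyond those multiples
occur only inside true events, making the generated event structure
assertable.

Per-participant nod style is the mechanism that separates the two CV
protocols: a forest trained on deep-slow nodders must recognize a
shallow-fast one, so LOPO macro F1 is bounded above by the random-split
score in expectation — the qualitative ordering real meeting data shows.

What the generator does **not** emulate: tracker dropouts and identity
switches, head rotations coupled to landmark positions, co-articulated
nodding-while-speaking, camera motion, lighting, or realistic facial
geometry. Passing tests therefore demonstrate that the pipeline's mechanics
are correct and that it recovers well-separated oscillatory events; they do
not certify the absolute F1 levels reachable on real recordings, which are
substantially noisier (synthetic macro F1 here is ≈ 0.95–0.98, where real
meeting data yields ≈ 0.6–0.7).

## Problem sizes

The default synthetic study uses 8 participants × 300 s (≈ 9 000 frames,
561 windows each, ≈ 750 windows after balancing) for the recognition scores,
and 24 participants × 300 s (> 400 events per class) for the duration
calibration — large enough for stable estimates while keeping a full run in
tens of seconds on one core.

## Known limitations

- The 60-feature composition is a documented reconstruction (10 + 4 time
  values and 13 + 3 frequency values per channel); other compositions with
  the same total are conceivable.
- Integer label codes (other = 0, nodding = 1, speaking = 2) are a package
  convention, as is the half-open interval membership.
- The lip distance is camera-distance dependent; transfer across recording
  setups would need a normalization the default pipeline deliberately omits.
- Simultaneous nodding and speaking is not modeled — one label per window.
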