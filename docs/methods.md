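# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `shopeeg`, and what the synthetic-data
tests do and do not establish about real recordings.

## Conventions

All times are seconds (float) from recording start; sample indices are
0-based; every window is half-open `[start, end)`; amplitudes are µV.
A time `t` maps to sample `floor(t * rate)`.

## Signal conditioning

* **Filtering.** Zero-phase (forward–backward) 4th-order Butterworth:
  a 0.5 Hz high-pass and a 48–52 Hz band-stop. The band-stop removes
  the 50 Hz mains line; a literal 48–52 Hz band-*pass* reading is
  available (`literal_bandpass=True`) for audit, but it would discard
  virtually the whole EEG spectrum and is not the default. Zero-phase
  filtering preserves decision-time alignment.
* **Average reference.** Each sample is re-expressed relative to the
  mean over included measurement channels; the operation is idempotent
  and makes the spatial mean exactly zero (≤1e-9 µV numerically).
* **Bad channels** are replaced by the inverse-distance weighted mean
  of their good montage neighbors. The neighbor graph connects
  electrodes closer than 1.6× the median nearest-neighbor distance of
  the 63-electrode 10/10 montage (ground AFz, reference FCz, 61 signal
  channels).
* **Artifact handling.** Human visual inspection and ICA-based ocular
  cleaning are out of scope (both require an operator and the full
  recording); the automated stand-in flags spans where any channel
  exceeds a configurable ±threshold (default 150 µV; off for synthetic
  data, which contains no artifacts) and drops overlapping episodes,
  with counts reported in the run manifest.

## Feature extraction

* **Hjorth parameters** are computed after removing the window mean, so
  activity equals the variance; otherwise DC offsets would dominate m0.
  Finite-difference derivatives are scaled by the sampling interval,
  giving mobility units of rad/s and matching the continuous
  definitions; the classic unscaled per-sample variant
  (`scale_derivatives=False`) is a monotone rescaling that leaves
  classification unchanged. Constant signals raise a degenerate-signal
  error rather than returning NaNs.
* **Identity used by the tests.** For sampled data the finite
  difference has transfer magnitude `2·fs·sin(π f / fs)`; the
  frequency-domain oracle in the test suite computes periodogram
  moments under this discrete mapping, which agrees with the
  time-domain moments to Parseval precision (≈0.01% at n = 1e5; the
  naive `(2πf)^k` moments agree only for signals far below Nyquist).
* **GFP anchoring.** GFP is the population standard deviation across
  channels per sample. Ties at the maximum resolve to the earliest
  sample (flat windows are legal). The τ-window is *centered* on the
  peak by default; "around the point of highest GFP" is direction-
  ambiguous, so a causal mode (window ending at the peak) is provided
  for real-time-style analyses. Windows crossing the recording bounds
  are shifted minimally to fit — never zero-padded, since padding
  corrupts the Hjorth moments; shifts are counted in the bookkeeping.
* **Normalization** is per snippet across the 61 channels ("applied
  over feature vectors"), making each snippet scale-free. This is the
  faithful default even though it discards the global mobility level
  (see Limitations); per-feature normalization fitted on training data
  only is the leakage-safe alternative for ML-style workflows.
* **Morlet band power** (theta 5–7 Hz, alpha 8–13 Hz, 1 Hz grid) uses
  7-cycle complex Morlet wavelets with Gaussian sd `n_cycles/(2πf)`
  truncated at ±3 sd, convolved in 'same' mode. A window shorter than
  7 cycles of the band's lowest frequency raises an error rather than
  silently truncating: 1200 ms therefore supports alpha but not theta
  (which needs 1400 ms).
* Hjorth *activity* is extracted but excluded from default model runs;
  only mobility and complexity are decoding features.

## Decoding and evaluation

* Model families and pinned hyperparameters: LDA (SVD solver),
  logistic regression (L2, max_iter 200), k-NN with k = 5, SVM with
  RBF kernel (C = 1, kernel scale `gamma='scale'`, unlimited
  iterations by default — an iteration cap is recorded as a
  non-convergence flag, never silently dropped), random forest with
  100 trees. No resampling or class weighting by default; a
  balanced-weights mode exists.
* **5-fold CV** is stratified by label over snippets (each fold an
  80/20 split). Because the four jittered snippets of one page view
  are near-duplicates, snippet-level folds leak episode and subject
  identity; this is intentional and measured (see the leakage
  diagnostic below).
* **LOSO CV** holds out all snippets of one subject per fold.
  `CVResults` reports per-subject fold scores, their unweighted mean,
  and `pooled` — the balanced accuracy of the pooled out-of-fold
  predictions. The pooled statistic is the calibrated headline: with
  only ~8 views per subject, held-out subjects often miss classes
  entirely, and the per-subject balanced accuracy of a majority-class
  predictor is then 1.0, biasing the subject mean far above chance
  under a null generator. (This small-test-set artifact also produces
  the seemingly paradoxical pattern of a chance-level linear model
  scoring much higher under LOSO than under 5-fold.)
* **Balanced accuracy** is the unweighted mean of per-class recall.
* **Channel importance**: mean decrease in impurity (mean ± sd across
  trees, normalized to sum 1) is the default; permutation importance
  (balanced-accuracy drop under per-channel shuffling on a held-out
  table, mean ± sd over repeats) is offered as the unbiased-cardinality
  alternative, since the two are often conflated.

## Synthetic cohorts

The generator emulates the statistical skeleton of a free-browsing
shopping study:

* **Sessions.** Each subject views `Poisson(8.38/μ)` products, each
  with 1–6 views (geometric, p = 0.5, capped; mean μ ≈ 1.97), view
  durations lognormal with mean 9.82 s and sd 10.89 s (floored at
  0.6 s), exponential inter-view gaps. Product fates (none /
  cart-only / buy, cart preceding buy with probability 0.4 for
  multi-view bought products) are drawn with probabilities solved
  analytically from the view-count distribution so that the *expected
  view-level* label mix equals 24% buy / 25% cart / 51% no-buy — a
  carted-then-bought product contributes exactly half its views to
  each label in expectation. Cart-removal events never occur.
* **EEG.** 61 signal channels at 500 Hz: 1/f² background (2 µV, band-
  limited at 45 Hz), band-limited flat measurement noise (0.75 µV,
  45 Hz), an alpha source (10 µV, Gaussian topography centered on Oz,
  slow amplitude modulation of depth 0.15) and a theta source (4 µV,
  centered on Fz). Each subject draws a baseline alpha-frequency
  offset (sd 0.5 Hz). The steep spectral decay matters: the Hjorth
  moments are ω²-weighted, so physically implausible near-Nyquist
  power would swamp any band-limited effect.
* **Planted effect.** During the final `min(view duration, 2 s)`
  before each decision time the alpha center frequency shifts by
  `effect_size × δ_label` with δ = (−1, +0.5, +1) for (no-buy, cart,
  buy); cart sits close to buy because both express a positive
  purchase attitude — the stated rationale for merging them in
  two-class tagging. Hjorth mobility is the spectral mean frequency,
  so the effect is recoverable by exactly the feature the pipeline
  extracts. The effect size is a calibration knob, not an estimate of
  any real neural effect: no published characterization of what
  distinguishes the classes neurally exists.
* **Determinism.** Per-subject generators are spawned from the config
  seed via `SeedSequence`, so cohorts are byte-reproducible and each
  subject's draw is independent of cohort size.

### What the synthetic tests show — and what they do not

Passing the calibration/recovery surface shows that the pipeline is
correctly wired (no label leakage through the feature path; planted
spectral structure of realistic magnitude is recovered; snippet-level
CV measurably overstates subject-level generalization). It does *not*
show that real purchase decisions are decodable at any particular
accuracy: the generator contains no artifacts, no volume-conduction
forward model, no non-stationarity beyond amplitude modulation, and a
single known effect mechanism. Absolute accuracies on synthetic
cohorts are properties of the chosen calibration, not predictions
about human data.

## Problem sizes used in the shipped checks

Cohorts of 12 subjects (≈100 page views, ≈400 augmented snippets) for
calibration and recovery, 5 generator seeds for the null, single seeds
elsewhere; τ = 1200 ms and Hjorth mobility as the default feature.
These sizes give binomial 95% bands of about ±0.05 around chance,
tight enough to detect miscalibration while keeping the whole suite
runnable on a laptop CPU in a few minutes.

## Known limitations

* Per-snippet min–max normalization discards the global mobility
  level; effects expressed as a uniform shift across all channels are
  attenuated, surviving only through topographic contrast. Raw
  (unnormalized) features decode the planted effect substantially
  better; the normalized default is kept for fidelity to the method.
* The EDF writer is minimal (single data record, 16-bit, symmetric
  physical scaling) — adequate for interchange and round-trip tests,
  not a general-purpose EDF library. BrainVision support is read-only.
* ICA artifact removal, eye-tracking video processing and real-time
  operation are out of scope.
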