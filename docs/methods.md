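# Methods

## The recognition problem

Congestive heart failure changes the ECG's subband energy distribution:
QRS complexes broaden and lose amplitude, T waves flatten, and the rhythm
becomes faster and more irregular than normal sinus rhythm. The package
detects this signature at the *segment* level — no beat detection or RR
extraction — on ~10 s single-lead excerpts, so that the whole decision
reduces to comparing one feature vector against two class templates.

## Preprocessing

All segments are made comparable before feature extraction: resampled to a
common rate (default 250 Hz, polyphase rational resampling), band-pass
filtered to 0.5–40 Hz, and divided by their maximum absolute amplitude so
the peak is exactly 1. The 0.5 Hz corner removes baseline wander; 40 Hz is
the upper edge of the ambulatory recording bandwidth the method targets.
Percentage-energy features are scale-invariant anyway; peak normalization
is kept because the distance-based confirmation scores are not, and it
keeps signals plot-comparable.

The default band-pass is an **ideal zero-phase spectral projection**:
frequency bins outside [0.5, 40] Hz are zeroed. A projection is exactly
idempotent, introduces no edge transients, and passes band-limited signals
through unchanged. We evaluated zero-phase forward–backward Butterworth
filtering first and rejected it as the default: a recursive high-pass with
a 0.5 Hz corner rings for several seconds, so on a 10 s segment its edge
transients (~0.25 peak amplitude, ~0.01 even mid-segment) dominate the
distortion budget, and its gradual rolloff makes repeated preprocessing
drift. The Butterworth realization remains available via
`PreprocessConfig(filter_mode="butterworth", filter_order=...)` for users
who want the classic recursive filter.

## WAFE features

The segment is decomposed with an orthonormal wavelet packet filter bank
(default `db5`) to level *L* = 5, giving *Q* = 2^L = 32 terminal subbands.
Boundary handling is periodization, which makes the transform exactly
energy-preserving (Parseval) and perfectly reconstructing — but only when
the signal length is divisible by 2^L. The decomposition therefore
analyzes the largest such prefix: a 2500-sample segment is analyzed over
its first 2496 samples (16 ms discarded, the same drop-the-remainder
policy used in framing). Each terminal node is reconstructed to a
full-length subsignal through the inverse filter bank with its siblings
zeroed; the per-node reconstruction is implemented as an `idwt` upsampling
chain, which is an order of magnitude faster than instantiating one
wavelet-packet object per node and is verified against that independent
route in the tests.

Each subsignal is cut into *Z* equal non-overlapping frames (default
*Z* = 5, i.e. 2 s frames covering roughly 2–3 beats; trailing remainder
samples are dropped). Within each frame, node energies are normalized by
the frame's total across nodes — so every frame vector sums to exactly
100 — and the *Z* frame vectors are averaged. Normalizing within-frame
rather than against the whole-segment total is a deliberate choice: it
preserves the sum-to-100 contract per frame and makes the average a proper
mixture of per-frame energy distributions. With *Z* = 1 the feature equals
the per-node coefficient-energy percentages of the whole segment, which is
the property the tests exploit as an oracle.

Comparison extractors share the tree and the framing: Shannon entropy of
the normalized squared coefficients (0·log 0 := 0), log-energy entropy
Σ log c² with a 10⁻¹² guard, SURE entropy Σ min(c², τ²) with
τ = √(2 log(n log₂ n)), and the per-node mean of a Hann-window Welch PSD
(256-sample segments, 50% overlap, or the frame length if shorter). These
entropy parameterizations are the standard wavelet-toolbox definitions,
adopted here because the comparison extractors exist only to be ranked
against WAFE.

Node ordering is natural (filter-bank) by default; frequency ordering is a
flag. Ordering permutes the vector and must simply be common to all
vectors compared.

## Confirmation functions and decision rule

A class model is the element-wise mean of (by default 15) training feature
vectors. For a tested vector *Y*, hypothesized model *x* and background
model *b*:

* **PRDS** `= 100·‖Y−m‖/‖Y‖` against each model; confirm when the ratio
  PRDS(Y,x)/PRDS(Y,b) is strictly < 1.
* **LDSR** `= log[(‖Y−x‖² + ε)/(‖Y−b‖² + ε)]`, ε = 10⁻¹²; confirm when
  ≤ 0. Natural log — only the sign is thresholded, so the base is
  behavior-neutral; the ε-guard replaces any complex-log concerns at zero
  distance. Computed as a difference of logs so swapping the models
  negates the value exactly.
* **CCR** `= CC(Y,x)/CC(Y,b)` (Pearson); confirm when strictly > 1. If
  CC(Y,b) is exactly zero the ratio is a signed-infinity sentinel and the
  threshold is decided by the sign of CC(Y,x).

The segment is accepted as CHF only when all three confirm. Boundary ties
follow the literal threshold blocks: a PRDS ratio of exactly 1 and a CCR
of exactly 1 do **not** confirm, an LDSR of exactly 0 does. Consequently
`confirm(Y,x,b)` and `confirm(Y,b,x)` can both be true only on a threshold
tie.

The three fixed thresholds yield a single operating point, so ROC curves
sweep the continuous score **−LDSR** — the unique smooth antisymmetric
scalar among the three — which is harness plumbing, not part of the
decision rule.

## Evaluation

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), positive predictivity
= TP/(TP+FP), each ×100; the *recognition rate* is their arithmetic mean.
A zero denominator raises an explicit error naming the measure. The one
exception is inside the benchmark harness: under heavy noise the AND rule
can confirm *nothing* (TP+FP = 0), making positive predictivity 0/0; the
harness scores it 0% — the most pessimistic value — so noise-degradation
sweeps remain well defined. ROC/AUC uses the full threshold sweep with
trapezoidal integration; AUC equals the tie-aware normalized Mann–Whitney
U statistic, which the tests verify by brute-force pair counting.

The benchmark builds both models from the first 15 segments of each class
(excluded from testing) and tests the remainder — 150 + 150 by default,
mirroring the scale of a few hundred test segments per pairing. Noise
experiments inject AWGN into the *raw* test segments before preprocessing;
the SNR is defined against the clean segment's mean-square power and the
noise realization is rescaled so the realized SNR is exact, not merely
exact in expectation.

## Synthetic data: what it emulates and what it does not

Beats are sums of Gaussian bumps for P, Q, R, S, T at fixed offsets around
an on-grid R peak; RR intervals are lognormal (guaranteeing positivity)
with class-specific mean heart rate and coefficient of variation. The four
presets encode the *kind* of contrast the method exploits:

| preset | HR (bpm) | RR CV | distinguishing morphology |
|--------|---------|-------|---------------------------|
| NSR | 72 | 0.03 | full PQRST, sharp R (amp 1.0, σ 12 ms) |
| CHF | 95 | 0.11 | reduced R (0.55), broadened QRS (σ 28 ms), flat T |
| AF | 110 | 0.25 | no P wave, 8–12 Hz fibrillatory baseline (amp 0.15) |
| PEB | 72 | 0.05 | 25% of beats replaced by wide P-less ectopics (amp 1.3) |

plus white measurement noise at a 30 dB SNR floor. These values are
package design choices selected once for physiological plausibility; they
are **not** claims about clinical CHF morphology, and the generator is not
a clinically realistic simulator (no respiratory modulation, no
heart-rate-dependent QT adaptation, no electrode artifacts, single lead
only). Passing the benchmark therefore demonstrates that the pipeline
discriminates classes whose subband-energy signatures differ in the
intended way — it does not certify performance on hospital recordings,
whose absolute recognition rates depend on data this repository does not
ship.

One consequence worth knowing: under 0 dB AWGN the flat noise spectrum
pulls every feature vector toward the broadband (NSR-like) profile, so the
AND rule may reject all segments even though the −LDSR ranking (AUC) stays
high — fixed thresholds degrade much faster than the underlying score.

## Numerical choices and degenerate inputs

* Periodization + length-divisibility gives Parseval to ~10⁻¹⁶ relative;
  the tests enforce 10⁻⁶ (Parseval) and 10⁻⁸ (reconstruction).
* All-zero signals, frames, or vectors raise degenerate-input errors
  rather than propagating NaN (normalization, percentage energy, PRDS,
  correlation).
* CSV I/O writes `%.17g` and parses with round-trip float precision, so
  write-then-read reproduces samples bit-exactly.
* AWGN is deterministic per seed; dataset generation derives independent
  per-segment seeds (< 2³¹) from one master seed.
* WFDB support is a minimal reader/writer for the `.hea`/`.dat` dialect
  (formats 16 and 212, single-segment records, physical units
  (digital − baseline)/gain), written for this package.

## Known limitations

* Segment lengths not divisible by 2^L lose up to 2^L − 1 trailing samples
  to the analysis prefix (≤ 124 ms at 250 Hz, level 5).
* The CCR criterion is undefined for zero-variance vectors and
  non-confirming whenever Y anti-correlates with the background model even
  if Y matches the hypothesized model exactly — an inherent property of
  the correlation-ratio rule, relevant only for adversarial inputs, since
  class-average energy profiles of real rhythms correlate positively.
* The decision rule has no tunable operating point; applications needing
  one should threshold the −LDSR score directly.
* Multi-class recognition is expressed as repeated one-vs-background
  confirmations; no calibration across pairings is attempted.
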