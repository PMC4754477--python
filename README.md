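# wafecg

Recognition of congestive heart failure (CHF) from short single-lead ECG
segments by **wavelet-packet average-framing percentage-energy (WAFE)**
features and three threshold-based **confirmation functions**.

Congestive heart failure alters both the rhythm and the morphology of the
ECG, and hence how the signal's energy is distributed over frequency
subbands. This package is for signal-processing researchers and engineers
who want a simple, training-free CHF detector that operates on ~10-second
segments (~12 beats at 250 Hz) without beat detection, and a fully
reproducible harness — including a synthetic four-class ECG generator
(NSR, CHF-like, AF-like, PEB-like) — to evaluate it with, offline.

## Method

**Features.** A preprocessed segment (band-passed 0.5–40 Hz, peak-normalized)
is decomposed into the *Q* = 2^L terminal subbands of a level-*L* wavelet
packet tree (default db5, *L* = 5, *Q* = 32). Each terminal node *q* is
reconstructed to a full-length subsignal *u_q*(*t*), cut into *Z* equal
frames, and the per-frame percentage energies are averaged:

    afe_q = (1/Z) · Σ_z  100 · E(u_q, frame z) / Σ_q' E(u_q', frame z)

giving a length-*Q* vector **AFE** = (afe_1, …, afe_Q) that is nonnegative,
sums to 100, and is invariant to amplitude scaling. Comparison extractors
over the same tree: Shannon / log-energy / SURE wavelet entropies (WPSE,
WPLE, WPSUE) and per-node mean Welch PSD (WPAP).

**Classification.** A class is modelled by the mean feature vector of 15
training segments. A tested vector *Y* is compared with the hypothesized
model *x* (CHF) and a background model *b* (NSR, AF or PEB) by

* PRDS ratio: `PRDS(Y,x)/PRDS(Y,b) < 1` where `PRDS(Y,m) = 100·‖Y−m‖/‖Y‖`,
* LDSR: `log(‖Y−x‖² / ‖Y−b‖²) ≤ 0`,
* CCR: `CC(Y,x)/CC(Y,b) > 1` (Pearson correlations),

and accepted as CHF only when **all three** confirm. Performance is scored
by sensitivity, specificity, positive predictivity, their mean (the
*recognition rate*), and ROC/AUC over the continuous score −LDSR; noise
robustness is probed with additive white Gaussian noise at exact SNR.

## Worked example

```python
from wafecg import PRESETS, synth_dataset, preprocess, extract_afe, build_model, confirm

# 16 segments per class: 15 build each model, the 16th is tested
chf = synth_dataset([PRESETS["CHF"]], 16, seed=42)
nsr = synth_dataset([PRESETS["NSR"]], 16, seed=43)
feats = {c: [extract_afe(preprocess(s)) for s in segs]
         for c, segs in (("CHF", chf), ("NSR", nsr))}
chf_model = build_model(feats["CHF"][:15], "CHF")
nsr_model = build_model(feats["NSR"][:15], "NSR")

res = confirm(feats["CHF"][15], chf_model, nsr_model)
print(f"PRDS ratio = {res.prds_ratio:.3f}  (confirm: {res.confirm_prds})")
print(f"LDSR       = {res.ldsr:+.3f}  (confirm: {res.confirm_ldsr})")
print(f"CCR        = {res.ccr:.3f}  (confirm: {res.confirm_ccr})")
print(f"decision   = {'CHF' if res.confirmed else 'not CHF'}")
```

prints

```
PRDS ratio = 0.212  (confirm: True)
LDSR       = -3.105  (confirm: True)
CCR        = 1.035  (confirm: True)
decision   = CHF
```

The held-out CHF segment sits five times closer to the CHF model than to
the NSR model (PRDS ratio 0.212), its squared-distance log-ratio is
negative, and it correlates better with the CHF model — all three
functions confirm, so the segment is accepted as CHF.

The same workflow is available from the shell:

```sh
wafecg synth --class CHF --n 16 --seed 42 --out chf/
wafecg extract chf/*.csv --label CHF --out chf.csv
wafecg model chf.csv --class CHF --out chf.json
wafecg confirm --model chf.json --background nsr.json --input test_segment.csv
wafecg benchmark --classes NSR,CHF --n-test 150 --snr-db 5 --seed 1 --out report/
```

Real recordings in PhysioNet WFDB format (formats 16 and 212) or plain CSV
can be read with `wafecg.read_ecg` / `wafecg ingest`.

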